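"""Forward simulator for noninvasive genetic monitoring of a two-sex population.

The generator emulates the data-producing process that the downstream analysis
assumes: a population of individually distinct multilocus microsatellite
genotypes is sampled over a robust-design calendar (primary sampling occasions
= field sessions, secondary occasions = sampling days).  Between sessions the
population is open — individuals survive with sex-specific probability and may
temporarily leave the study area (Markovian temporary emigration) — while
within a session it is closed.  Every capture (a fecal sample that yields a
genotype) is correctly attributed to its individual with probability ``alpha``;
otherwise a *ghost*, a unique erroneous genotype that appears exactly once, is
created.  Capture events are then expanded into PCR replicate tables carrying
per-replicate allelic dropout, false alleles, missing replicates, and
sex-marker dropout in males.

Ground truth (true genotypes, states, capture events, ghost records) is
retained so that recovery of individuals, error rates and demographic
parameters can be tested against known values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .histories import FALL, SPRING, CaptureHistorySet

FEMALE = "F"
MALE = "M"

#: Default per-locus allele frequencies: seven microsatellite loci with the
#: allele counts observed in an alpine mountain-hare panel (3, 5, 7, 2, 6, 3,
#: 5 alleles) and skewed frequency spectra giving expected heterozygosities of
#: roughly 0.14-0.64.
DEFAULT_LOCI: dict[str, np.ndarray] = {
    "Lsa1": np.array([0.45, 0.35, 0.20]),
    "Lsa3": np.array([0.78, 0.10, 0.06, 0.04, 0.02]),
    "Sat5": np.array([0.68, 0.10, 0.06, 0.05, 0.05, 0.03, 0.03]),
    "Sat8": np.array([0.925, 0.075]),
    "Sol30": np.array([0.74, 0.08, 0.06, 0.05, 0.04, 0.03]),
    "Sol33": np.array([0.55, 0.30, 0.15]),
    "Sol8": np.array([0.765, 0.10, 0.06, 0.05, 0.025]),
}

# Season- and sex-specific defaults for the capture process, matching the
# weighted-mean estimates of the monitored population (capture probability p,
# recapture probability c, correct-identification probability alpha).
DEFAULT_P = {
    (FEMALE, SPRING): 0.26,
    (MALE, SPRING): 0.26,
    (FEMALE, FALL): 0.25,
    (MALE, FALL): 0.17,
}
DEFAULT_C = {
    (FEMALE, SPRING): 0.34,
    (MALE, SPRING): 0.44,
    (FEMALE, FALL): 0.22,
    (MALE, FALL): 0.21,
}
DEFAULT_ALPHA = {
    (FEMALE, SPRING): 0.95,
    (MALE, SPRING): 0.77,
    (FEMALE, FALL): 0.81,
    (MALE, FALL): 0.77,
}

SexSeason = Mapping[tuple[str, str], float]

# Allele-length namespace reserved for fabricated ghost genotypes; real locus
# allele ladders start at 100 and stay far below this.
_GHOST_ALLELE_BASE = 5000
_GHOST_PATTERN_BASE = 1000


def _as_sex_season(value: float | SexSeason) -> dict[tuple[str, str], float]:
    if isinstance(value, Mapping):
        out = dict(value)
    else:
        out = {}
        for sex in (FEMALE, MALE):
            for season in (SPRING, FALL):
                out[(sex, season)] = float(value)
    for k, v in out.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0,1] for {k}: {v}")
    return out


@dataclass
class SimulationConfig:
    """Study conditions for the forward simulator.

    Probabilities are per the unit given in each comment; ``p_capture``,
    ``c_recapture`` and ``alpha`` accept either a scalar or a mapping keyed by
    ``(sex, season)``.
    """

    allele_freqs: Mapping[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_LOCI.items()}
    )
    n_females: int = 12
    n_males: int = 16
    phi_f: float = 0.90          # apparent survival per between-PSO interval
    phi_m: float = 0.76
    gamma_dprime: float = 0.05   # P(on-site -> temporary emigrant)
    gamma_prime: float = 0.77    # P(emigrant stays off-site)
    p_capture: float | SexSeason = field(default_factory=lambda: dict(DEFAULT_P))
    c_recapture: float | SexSeason = field(default_factory=lambda: dict(DEFAULT_C))
    alpha: float | SexSeason = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    dropout_rate: float = 0.02            # per heterozygous replicate-locus
    false_allele_rate: float = 0.002      # per replicate-locus
    missing_replicate_rate: float = 0.15  # per replicate-locus
    sry_dropout: float = 0.25             # per replicate, males only
    n_pso: int = 10
    sso_per_pso: int | Sequence[int] = 5
    seasons: Sequence[str] | None = None  # default: alternating spring/fall
    recruits_per_interval: tuple[int, int] = (0, 0)  # (females, males)
    n_replicates: int = 3
    n_pattern_loci: int = 2        # qualitative pattern loci (scored per sample)
    pattern_class_count: int = 12  # distinguishable peak-pattern classes per locus
    systematic_fraction: float = 0.19  # share of samples from the systematic grid
    seed: int = 0

    def __post_init__(self) -> None:
        self.allele_freqs = {k: np.asarray(v, float) for k, v in self.allele_freqs.items()}
        for locus, freqs in self.allele_freqs.items():
            if freqs.ndim != 1 or len(freqs) < 1:
                raise ValueError(f"allele frequencies for {locus} must be a 1-D vector")
            if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-12:
                raise ValueError(f"allele frequencies for {locus} must sum to 1")
        if self.n_pso < 1:
            raise ValueError("need at least one primary occasion")
        if isinstance(self.sso_per_pso, int):
            self.sso_per_pso = [self.sso_per_pso] * self.n_pso
        self.sso_per_pso = [int(k) for k in self.sso_per_pso]
        if len(self.sso_per_pso) != self.n_pso or min(self.sso_per_pso) < 1:
            raise ValueError("sso_per_pso must give >=1 SSO for every PSO")
        if self.seasons is None:
            self.seasons = [SPRING if t % 2 == 0 else FALL for t in range(self.n_pso)]
        self.seasons = list(self.seasons)
        if len(self.seasons) != self.n_pso:
            raise ValueError("one season label per PSO required")
        if set(self.seasons) - {SPRING, FALL}:
            raise ValueError("seasons must be 'spring' or 'fall'")
        for name in (
            "phi_f", "phi_m", "gamma_dprime", "gamma_prime", "dropout_rate",
            "false_allele_rate", "missing_replicate_rate", "sry_dropout",
            "systematic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        self.p_capture = _as_sex_season(self.p_capture)
        self.c_recapture = _as_sex_season(self.c_recapture)
        self.alpha = _as_sex_season(self.alpha)
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("negative population sizes")
        if self.n_females + self.n_males == 0 and sum(self.recruits_per_interval) == 0:
            raise ValueError("empty population: no individuals and no recruits")
        if self.n_replicates < 1:
            raise ValueError("need at least one PCR replicate")

    @property
    def loci(self) -> list[str]:
        return list(self.allele_freqs)

    @property
    def pattern_loci(self) -> list[str]:
        return [f"Pat{i + 1}" for i in range(self.n_pattern_loci)]

    def allele_lengths(self, locus: str) -> np.ndarray:
        """Integer fragment lengths backing the allele indices of ``locus``."""
        idx = self.loci.index(locus)
        n = len(self.allele_freqs[locus])
        return 100 + 20 * idx + 2 * np.arange(n)


@dataclass
class CaptureEvent:
    individual: int
    pso: int
    sso: int
    is_ghost: bool
    ghost_id: int | None = None


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated monitoring study."""

    config: SimulationConfig
    sexes: list[str]
    genotypes: list[dict[str, tuple[int, int]]]
    patterns: list[dict[str, int]]
    entry_pso: np.ndarray          # first PSO at which each individual exists
    alive: np.ndarray              # (n, n_pso) bool
    onsite: np.ndarray             # (n, n_pso) bool; onsite implies alive
    capture_events: list[CaptureEvent]
    ghost_genotypes: list[dict[str, tuple[int, int]]]
    ghost_patterns: list[dict[str, int]]

    @property
    def n_individuals(self) -> int:
        return len(self.sexes)

    @property
    def ghost_records(self) -> list[CaptureEvent]:
        return [e for e in self.capture_events if e.is_ghost]

    def captured_individuals(self) -> set[int]:
        return {e.individual for e in self.capture_events if not e.is_ghost}


def _sample_genotype(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    geno = {}
    for locus, freqs in config.allele_freqs.items():
        lengths = config.allele_lengths(locus)
        a, b = rng.choice(lengths, size=2, p=freqs)
        geno[locus] = (min(a, b), max(a, b))
    return geno


def simulate_population(config: SimulationConfig) -> SimulatedTruth:
    """Run the demographic and capture process forward under ``config``.

    States evolve as a Markov chain per individual: survival with the
    sex-specific ``phi``, transition on-site -> off-site with ``gamma_dprime``
    and off-site -> off-site with ``gamma_prime``.  Within a PSO, captures are
    drawn per SSO with ``p`` until the first capture of the session, then with
    ``c``.  Each capture is misidentified with probability ``1 - alpha``,
    spawning a ghost record with a unique fabricated genotype.
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_pso

    sexes: list[str] = [FEMALE] * config.n_females + [MALE] * config.n_males
    entry = [0] * len(sexes)
    # recruits enter between PSOs, alive and on-site
    for t in range(1, T):
        rf, rm = config.recruits_per_interval
        sexes += [FEMALE] * rf + [MALE] * rm
        entry += [t] * (rf + rm)

    n = len(sexes)
    genotypes = [_sample_genotype(config, rng) for _ in range(n)]
    patterns = [
        {pl: int(rng.integers(config.pattern_class_count)) for pl in config.pattern_loci}
        for _ in range(n)
    ]

    alive = np.zeros((n, T), dtype=bool)
    onsite = np.zeros((n, T), dtype=bool)
    for i in range(n):
        e = entry[i]
        alive[i, e] = True
        onsite[i, e] = True
        for t in range(e + 1, T):
            if not alive[i, t - 1]:
                break
            phi = config.phi_f if sexes[i] == FEMALE else config.phi_m
            if rng.random() >= phi:
                break
            alive[i, t] = True
            if onsite[i, t - 1]:
                onsite[i, t] = rng.random() >= config.gamma_dprime
            else:
                onsite[i, t] = rng.random() >= config.gamma_prime

    events: list[CaptureEvent] = []
    ghost_genotypes: list[dict[str, tuple[int, int]]] = []
    ghost_patterns: list[dict[str, int]] = []
    for t in range(T):
        season = config.seasons[t]
        for i in range(n):
            if not onsite[i, t]:
                continue
            sex = sexes[i]
            p = config.p_capture[(sex, season)]
            c = config.c_recapture[(sex, season)]
            a = config.alpha[(sex, season)]
            captured_before = False
            for j in range(config.sso_per_pso[t]):
                prob = c if captured_before else p
                if rng.random() >= prob:
                    continue
                captured_before = True
                if rng.random() < a:
                    events.append(CaptureEvent(i, t, j, is_ghost=False))
                else:
                    gid = len(ghost_genotypes)
                    base = _GHOST_ALLELE_BASE + 2 * gid * len(config.loci)
                    ghost_genotypes.append(
                        {
                            locus: (base + 2 * k, base + 2 * k)
                            for k, locus in enumerate(config.loci)
                        }
                    )
                    ghost_patterns.append(
                        {pl: _GHOST_PATTERN_BASE + gid for pl in config.pattern_loci}
                    )
                    events.append(CaptureEvent(i, t, j, is_ghost=True, ghost_id=gid))

    return SimulatedTruth(
        config=config,
        sexes=sexes,
        genotypes=genotypes,
        patterns=patterns,
        entry_pso=np.asarray(entry),
        alive=alive,
        onsite=onsite,
        capture_events=events,
        ghost_genotypes=ghost_genotypes,
        ghost_patterns=ghost_patterns,
    )


def _corrupt_pair(
    pair: tuple[int, int],
    locus_pool: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    a, b = pair
    # allelic dropout: heterozygote loses one allele uniformly
    if a != b and rng.random() < config.dropout_rate:
        kept = a if rng.random() < 0.5 else b
        a = b = kept
    # false allele: one allele replaced by a novel length
    if rng.random() < config.false_allele_rate:
        candidates = [x for x in locus_pool if x not in (a, b)]
        novel = int(rng.choice(candidates)) if candidates else int(max(a, b, *locus_pool) + 2)
        if rng.random() < 0.5:
            a = novel
        else:
            b = novel
    # whole-replicate amplification failure
    if rng.random() < config.missing_replicate_rate:
        return (np.nan, np.nan)
    return (min(a, b), max(a, b))


def corrupt_to_replicates(
    truth: SimulatedTruth, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand capture events into a replicate genotype table plus sample truth.

    Every capture event yields one sample with ``n_replicates`` PCR replicates
    per locus.  Returns ``(replicates, samples)``: the raw replicate table the
    genotyping module reads (columns ``sample_id, session, day, method, locus,
    replicate, allele1, allele2, sry_amplified``) and a per-sample ground-truth
    sidecar (source individual, ghost status, true sex, pattern-locus classes).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)

    rep_rows = []
    sample_rows = []
    for k, ev in enumerate(truth.capture_events):
        sample_id = f"S{ev.pso + 1:02d}D{ev.sso + 1}-{k:04d}"
        session = f"P{ev.pso + 1:02d}-{config.seasons[ev.pso]}"
        method = "systematic" if rng.random() < config.systematic_fraction else "opportunistic"
        sex = truth.sexes[ev.individual]
        if ev.is_ghost:
            geno = truth.ghost_genotypes[ev.ghost_id]
            pattern = truth.ghost_patterns[ev.ghost_id]
        else:
            geno = truth.genotypes[ev.individual]
            pattern = truth.patterns[ev.individual]

        # sex marker amplifies per replicate in males only
        if sex == MALE:
            sry = rng.random(config.n_replicates) >= config.sry_dropout
        else:
            sry = np.zeros(config.n_replicates, dtype=bool)

        for locus in config.loci:
            pool = (
                config.allele_lengths(locus)
                if not ev.is_ghost
                else np.asarray(geno[locus])
            )
            for r in range(config.n_replicates):
                a1, a2 = _corrupt_pair(geno[locus], pool, config, rng)
                rep_rows.append(
                    {
                        "sample_id": sample_id,
                        "session": session,
                        "day": ev.sso + 1,
                        "method": method,
                        "locus": locus,
                        "replicate": r + 1,
                        "allele1": a1,
                        "allele2": a2,
                        "sry_amplified": bool(sry[r]),
                    }
                )
        row = {
            "sample_id": sample_id,
            "session": session,
            "pso": ev.pso + 1,
            "day": ev.sso + 1,
            "method": method,
            "source_individual": ev.individual,
            "is_ghost": ev.is_ghost,
            "ghost_id": ev.ghost_id,
            "true_sex": sex,
        }
        row.update({pl: pattern[pl] for pl in config.pattern_loci})
        sample_rows.append(row)

    replicates = pd.DataFrame(rep_rows)
    samples = pd.DataFrame(sample_rows)
    return replicates, samples


def histories_from_truth(
    truth: SimulatedTruth, include_ghosts: bool = True
) -> CaptureHistorySet:
    """Build the observed capture-history set directly from ground truth.

    Correctly identified captures of an individual become detections of its
    genotype; every ghost record contributes a unique single-detection
    history.  This is the error-free-genotyping shortcut past the replicate
    table (useful for testing the mark-recapture machinery in isolation).
    """
    config = truth.config
    T = config.n_pso
    max_sso = max(config.sso_per_pso)

    real_ids = sorted(truth.captured_individuals())
    index = {i: k for k, i in enumerate(real_ids)}
    n_ghosts = len(truth.ghost_genotypes) if include_ghosts else 0
    det = np.zeros((len(real_ids) + n_ghosts, T, max_sso), dtype=bool)
    groups = [truth.sexes[i] for i in real_ids]
    ids = [f"IND{i:04d}" for i in real_ids]
    for ev in truth.capture_events:
        if not ev.is_ghost:
            det[index[ev.individual], ev.pso, ev.sso] = True
        elif include_ghosts:
            det[len(real_ids) + ev.ghost_id, ev.pso, ev.sso] = True
    if include_ghosts:
        for g, ev in enumerate(truth.ghost_records):
            groups.append(truth.sexes[ev.individual])
            ids.append(f"GHOST{g:04d}")

    return CaptureHistorySet(
        detections=det,
        groups=np.asarray(groups, dtype=object),
        seasons=list(config.seasons),
        sso_counts=np.asarray(config.sso_per_pso),
        ids=ids,
    )
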