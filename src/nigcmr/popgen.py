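"""Population-genetic summaries of the identified individuals.

Per-locus statistics follow the usual microsatellite-panel conventions:
observed heterozygosity ``H_O``; unbiased expected heterozygosity
``H_E = (2n / (2n - 1)) (1 - sum p_i^2)``; polymorphic information content
``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``; the probability that two
unrelated individuals share a genotype
``P_ID = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2`` and its sibling analogue
``P_IDsib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4``,
both with plug-in allele frequencies; and the Chakraborty null-allele
estimate ``F_null = (H_E - H_O) / (H_E + H_O)``.  Multilocus identity
probabilities multiply across loci.  Hardy-Weinberg equilibrium is tested
with a Monte-Carlo exact test that permutes alleles among genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

AllelePair = tuple[int, int]


@dataclass
class LocusSummary:
    locus: str
    A: int                 # number of alleles
    N: int                 # individuals typed
    H_O: float | None      # None in frequency-only mode
    H_E: float
    PIC: float
    P_ID: float
    P_IDsib: float
    F_null: float | None


def allele_frequencies(genotypes: list[AllelePair]) -> dict[int, float]:
    """Relative allele frequencies from one locus' typed genotypes."""
    counts: dict[int, int] = {}
    for a, b in genotypes:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = sum(counts.values())
    return {allele: k / total for allele, k in sorted(counts.items())}


def _identity_terms(freqs: np.ndarray) -> tuple[float, float]:
    s2 = float(np.sum(freqs**2))
    s4 = float(np.sum(freqs**4))
    # sum_{i<j} (2 p_i p_j)^2 = 2 [ (sum p^2)^2 - sum p^4 ]
    p_id = s4 + 2.0 * (s2**2 - s4)
    p_idsib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return p_id, p_idsib


def summarize_locus_freqs(
    locus: str, freqs: dict[int, float] | np.ndarray, n_typed: int | None = None
) -> LocusSummary:
    """Frequency-only locus summary (no genotype-level observed statistics)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    pic = 1.0 - s2 - (s2**2 - s4)
    p_id, p_idsib = _identity_terms(p)
    if n_typed:
        n2 = 2 * n_typed
        h_e = (n2 / (n2 - 1)) * (1.0 - s2)
    else:
        h_e = 1.0 - s2
    return LocusSummary(
        locus=locus, A=len(p), N=n_typed or 0, H_O=None, H_E=h_e,
        PIC=pic, P_ID=p_id, P_IDsib=p_idsib, F_null=None,
    )


def summarize_locus(locus: str, genotypes: list[AllelePair]) -> LocusSummary:
    """Per-locus summary row from typed individual genotypes."""
    if len(genotypes) < 2:
        raise ValueError("need at least two typed individuals")
    n = len(genotypes)
    freqs = allele_frequencies(genotypes)
    p = np.asarray(list(freqs.values()))
    s2 = float(np.sum(p**2))
    h_o = sum(1 for a, b in genotypes if a != b) / n
    s4 = float(np.sum(p**4))
    h_e = (2 * n / (2 * n - 1)) * (1.0 - s2)
    pic = 1.0 - s2 - (s2**2 - s4)
    p_id, p_idsib = _identity_terms(p)
    if len(p) == 1:
        f_null = None  # monomorphic: undefined
    else:
        f_null = (h_e - h_o) / (h_e + h_o) if (h_e + h_o) > 0 else None
    return LocusSummary(
        locus=locus, A=len(p), N=n, H_O=h_o, H_E=h_e, PIC=pic,
        P_ID=p_id, P_IDsib=p_idsib, F_null=f_null,
    )


def multilocus_pid(per_locus: list[float] | np.ndarray) -> float:
    """Across-loci probability of identity: the product of per-locus values."""
    values = np.asarray(per_locus, float)
    if values.size == 0:
        raise ValueError("need at least one per-locus value")
    if np.any(values <= 0) or np.any(values > 1):
        raise ValueError("per-locus identity probabilities must be in (0, 1]")
    return float(np.prod(values))


def _log_table_prob(genotypes: list[AllelePair]) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene's formula: P = n! 2^h prod_k(m_k!) / ((2n)! prod_{i<=j} n_ij!)
    with h heterozygotes, m_k allele counts and n_ij genotype counts.
    """
    n = len(genotypes)
    geno_counts: dict[AllelePair, int] = {}
    allele_counts: dict[int, int] = {}
    h = 0
    for a, b in genotypes:
        key = (min(a, b), max(a, b))
        geno_counts[key] = geno_counts.get(key, 0) + 1
        allele_counts[a] = allele_counts.get(a, 0) + 1
        allele_counts[b] = allele_counts.get(b, 0) + 1
        if a != b:
            h += 1
    logp = gammaln(n + 1) + h * math.log(2.0) - gammaln(2 * n + 1)
    logp += sum(gammaln(m + 1) for m in allele_counts.values())
    logp -= sum(gammaln(k + 1) for k in geno_counts.values())
    return logp


def hwe_test(
    genotypes: list[AllelePair], n_mc: int = 10_000, seed: int | None = 0
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    Alleles are permuted among genotypes (conditioning on allele counts); the
    p-value is the fraction of permuted tables whose conditional probability
    is at most that of the observed table, with the add-one correction
    ``(1 + #{<=}) / (1 + n_mc)``.  Monomorphic loci return 1.
    """
    if len(genotypes) < 5:
        raise ValueError("need at least five typed individuals")
    alleles = np.asarray([x for pair in genotypes for x in pair])
    if len(np.unique(alleles)) == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = _log_table_prob(genotypes)
    n = len(genotypes)
    hits = 0
    work = alleles.copy()
    for _ in range(n_mc):
        rng.shuffle(work)
        perm = list(zip(work[:n], work[n:]))
        if _log_table_prob(perm) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_mc)


def locus_table(
    individuals: pd.DataFrame, loci: list[str], hwe: bool = False, seed: int = 0
) -> pd.DataFrame:
    """Per-locus summary table with an across-loci row.

    ``individuals`` holds one row per identified individual with per-locus
    ``"a1/a2"`` call strings (empty/NaN for untyped).  The across-loci row
    carries means of A, H_O and H_E and the product of the per-locus identity
    probabilities.
    """
    rows = []
    for locus in loci:
        genos = []
        for v in individuals[locus]:
            if isinstance(v, str) and "/" in v:
                a, b = v.split("/")
                genos.append((int(a), int(b)))
        s = summarize_locus(locus, genos)
        row = {
            "locus": s.locus, "A": s.A, "N": s.N, "H_O": s.H_O, "H_E": s.H_E,
            "PIC": s.PIC, "P_ID": s.P_ID, "P_IDsib": s.P_IDsib, "F_null": s.F_null,
        }
        if hwe:
            row["HWE_p"] = hwe_test(genos, seed=seed) if len(genos) >= 5 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    across = {
        "locus": "Across",
        "A": df["A"].mean(),
        "N": df["N"].median(),
        "H_O": df["H_O"].mean(),
        "H_E": df["H_E"].mean(),
        "PIC": df["PIC"].mean(),
        "P_ID": multilocus_pid(df["P_ID"]),
        "P_IDsib": multilocus_pid(df["P_IDsib"]),
        "F_null": np.nan,
    }
    if hwe:
        across["HWE_p"] = np.nan
    return pd.concat([df, pd.DataFrame([across])], ignore_index=True)
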