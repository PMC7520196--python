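"""Individual identification from accepted consensus genotypes.

Accepted multilocus consensus genotypes are grouped into unique individuals by
single-linkage clustering under an allele-mismatch threshold (default: merge
samples differing by at most two mismatched alleles, counting qualitative
pattern loci as two mismatches when their classes differ).  Sex conflicts
inside a cluster are resolved by reclassifying female-called samples that
group with male-called samples ("false females" — the Y-linked marker can
drop out in every replicate of a male sample, never the reverse).  Capture
histories for the mark-recapture stage are then binary detections per
(individual, session, day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import FEMALE, MALE
from .histories import CaptureHistorySet


def _parse_call(value) -> tuple[int, int] | None:
    if isinstance(value, tuple):
        return value
    if isinstance(value, str) and "/" in value:
        a, b = value.split("/")
        return (int(a), int(b))
    return None


def genotype_distance(
    g1: dict,
    g2: dict,
    loci: list[str],
    pattern_loci: list[str] | None = None,
) -> tuple[int, int]:
    """Mismatched-allele count between two genotypes over shared scored loci.

    Per locus scored in both genotypes, the mismatch is ``2 - m`` where ``m``
    is the size of a maximal pairing of the two allele multisets (0, 1 or 2
    mismatches).  Pattern loci contribute 2 mismatches when their classes
    differ, 0 when equal.  Loci missing in either genotype are skipped.

    Returns ``(mismatched_alleles, compared_loci)``; with zero comparable loci
    the distance is undefined and ``compared_loci`` is 0.
    """
    mism = 0
    compared = 0
    for locus in loci:
        p1 = _parse_call(g1.get(locus))
        p2 = _parse_call(g2.get(locus))
        if p1 is None or p2 is None:
            continue
        compared += 1
        # maximal multiset pairing of two allele pairs
        remaining = list(p2)
        matched = 0
        for a in p1:
            if a in remaining:
                remaining.remove(a)
                matched += 1
        mism += 2 - matched
    for pl in pattern_loci or []:
        c1, c2 = g1.get(pl), g2.get(pl)
        if c1 is None or c2 is None or (isinstance(c1, float) and np.isnan(c1)):
            continue
        compared += 1
        if c1 != c2:
            mism += 2
    return mism, compared


@dataclass
class Individual:
    """A cluster of samples sharing (up to tolerance) one multilocus genotype."""

    individual_id: str
    genotype: dict[str, tuple[int, int] | None]
    sex: str
    members: pd.DataFrame           # sample_id, session, day, method, sex
    false_female_members: list[str] = field(default_factory=list)
    pattern: dict[str, object] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.members)


def _modal(values: list) -> object | None:
    values = [v for v in values if v is not None]
    if not values:
        return None
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    # deterministic tie-break: smallest pair
    return sorted([v for v, k in counts.items() if k == best])[0]


def cluster_individuals(
    consensus: pd.DataFrame,
    loci: list[str],
    pattern_loci: list[str] | None = None,
    max_mismatch: int = 2,
    min_shared_loci: int = 5,
) -> list[Individual]:
    """Single-linkage grouping of accepted genotypes into individuals.

    Samples are processed in sorted ``sample_id`` order; two samples link when
    they share at least ``min_shared_loci`` comparable loci and differ by at
    most ``max_mismatch`` alleles (undefined distances never link).  Each
    individual's genotype is the modal allele pair per locus over its members,
    its sex is resolved male if any member was called male (female-called
    members of such clusters are flagged as false females), and identifiers
    are assigned in order of first detection.
    """
    df = consensus[consensus["accepted"]].sort_values("sample_id").reset_index(drop=True)
    pattern_loci = pattern_loci or []
    n = len(df)
    genos: list[dict] = []
    for _, row in df.iterrows():
        g = {locus: _parse_call(row[locus]) for locus in loci}
        for pl in pattern_loci:
            v = row.get(pl)
            g[pl] = None if (isinstance(v, float) and np.isnan(v)) else v
        genos.append(g)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            mism, compared = genotype_distance(genos[i], genos[j], loci, pattern_loci)
            if compared >= min_shared_loci and mism <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    # order individuals by first detection (session, day, sample_id)
    def first_detection(members: list[int]):
        sub = df.loc[members]
        return tuple(sub.sort_values(["session", "day", "sample_id"]).iloc[0][
            ["session", "day", "sample_id"]
        ])

    ordered = sorted(clusters.values(), key=first_detection)

    individuals = []
    for k, members in enumerate(ordered, start=1):
        sub = df.loc[members].copy()
        genotype = {
            locus: _modal([genos[m][locus] for m in members]) for locus in loci
        }
        pattern = {
            pl: _modal([genos[m][pl] for m in members]) for pl in pattern_loci
        }
        sexes = sub["sex"].tolist()
        if MALE in sexes:
            sex = MALE
            false_females = sub.loc[sub["sex"] == FEMALE, "sample_id"].tolist()
        else:
            sex = FEMALE
            false_females = []
        individuals.append(
            Individual(
                individual_id=f"IND{k:03d}",
                genotype=genotype,
                sex=sex,
                members=sub.reset_index(drop=True),
                false_female_members=false_females,
                pattern=pattern,
            )
        )
    return individuals


def false_female_count(individuals: list[Individual]) -> int:
    return sum(len(ind.false_female_members) for ind in individuals)


def individuals_table(individuals: list[Individual], loci: list[str]) -> pd.DataFrame:
    rows = []
    for ind in individuals:
        row = {
            "individual_id": ind.individual_id,
            "sex": ind.sex,
            "n_samples": ind.n_samples,
            "n_false_females": len(ind.false_female_members),
        }
        for locus in loci:
            pair = ind.genotype.get(locus)
            row[locus] = "" if pair is None else f"{pair[0]}/{pair[1]}"
        rows.append(row)
    return pd.DataFrame(rows)


def build_histories(
    individuals: list[Individual],
    calendar: pd.DataFrame,
    systematic_only: bool = False,
) -> CaptureHistorySet:
    """Binary detection histories per (individual, PSO, SSO).

    ``calendar`` maps sessions to the robust-design layout with columns
    ``session``, ``pso`` (1-based, chronological), ``season`` and ``n_days``.
    A member sample on day ``d`` of a session marks detection at SSO ``d``;
    with ``systematic_only`` samples collected opportunistically are ignored.
    Samples referencing a session absent from the calendar raise.
    """
    cal = calendar.sort_values("pso").reset_index(drop=True)
    session_to_pso = {s: int(p) - 1 for s, p in zip(cal["session"], cal["pso"])}
    seasons = cal["season"].tolist()
    sso_counts = cal["n_days"].to_numpy(dtype=int)
    T, max_sso = len(cal), int(sso_counts.max())

    det = np.zeros((len(individuals), T, max_sso), dtype=bool)
    groups = np.asarray([ind.sex for ind in individuals], dtype=object)
    ids = [ind.individual_id for ind in individuals]
    for i, ind in enumerate(individuals):
        members = ind.members
        if systematic_only:
            members = members[members["method"] == "systematic"]
        for _, row in members.iterrows():
            session = row["session"]
            if session not in session_to_pso:
                raise ValueError(f"sample {row['sample_id']} has unknown session {session}")
            t = session_to_pso[session]
            d = int(row["day"]) - 1
            if not 0 <= d < sso_counts[t]:
                raise ValueError(f"day {d + 1} outside session {session}")
            det[i, t, d] = True

    keep = det.any(axis=(1, 2))
    return CaptureHistorySet(
        detections=det, groups=groups, seasons=seasons, sso_counts=sso_counts, ids=ids
    ).subset(keep)


def calendar_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Derive a session calendar from sample metadata (session ordered as met).

    Expects columns ``session`` (sortable chronologically), ``day`` and, if
    present, ``season``; otherwise the season is parsed from the session label
    suffix (``...-spring`` / ``...-fall``).
    """
    sessions = sorted(samples["session"].unique())
    rows = []
    for t, s in enumerate(sessions, start=1):
        sub = samples[samples["session"] == s]
        if "season" in samples.columns:
            season = sub["season"].iloc[0]
        else:
            season = str(s).rsplit("-", 1)[-1]
        rows.append(
            {"session": s, "pso": t, "season": season, "n_days": int(sub["day"].max())}
        )
    return pd.DataFrame(rows)
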