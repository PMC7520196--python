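"""Multi-tube consensus genotype calling, sex determination and error rates.

Noninvasive samples are PCR-amplified in independent replicates (default
three).  A per-locus consensus is accepted under the standard multi-tube
rules: a homozygote only when every replicate amplified and agrees, a
heterozygote when at least two replicates agree and no more than two alleles
occur across the replicates.  A multilocus consensus genotype is accepted when
at least ``min_loci`` of the biallelic loci could be scored (default 6 of 7).
Sex is called male when any replicate amplified the Y-linked marker and female
otherwise.

Two error rates are quantified on the raw replicate table: the proportion of
missing replicate genotypes, and the proportion of (false) homozygote
replicates among all replicates of sample/locus combinations whose consensus
is heterozygous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "M"
FEMALE = "F"

AllelePair = tuple[int, int]

REPLICATE_COLUMNS = [
    "sample_id", "locus", "replicate", "allele1", "allele2",
]


def _is_missing(pair) -> bool:
    if pair is None:
        return True
    a, b = pair
    missing = (a is None or (isinstance(a, float) and math.isnan(a)),
               b is None or (isinstance(b, float) and math.isnan(b)))
    if missing[0] != missing[1]:
        raise ValueError("a replicate must have both alleles or neither")
    return missing[0]


def call_consensus_locus(replicates: list[AllelePair | None]) -> AllelePair | None:
    """Consensus allele pair for one sample/locus, or ``None`` for no call.

    ``replicates`` holds one allele pair (order-free) or ``None``/NaN-pair per
    replicate slot.  Homozygote consensus requires all slots present and
    identical; heterozygote consensus requires at least two concordant
    replicates and at most two distinct alleles across all non-missing
    replicates.
    """
    present = []
    for pair in replicates:
        if _is_missing(pair):
            continue
        a, b = pair
        present.append((min(a, b), max(a, b)))
    if not present:
        return None

    alleles = set()
    for a, b in present:
        alleles.update((a, b))

    counts: dict[AllelePair, int] = {}
    for pair in present:
        counts[pair] = counts.get(pair, 0) + 1

    # homozygote: every replicate slot amplified and agrees
    first = present[0]
    if (
        first[0] == first[1]
        and len(present) == len(replicates)
        and all(p == first for p in present)
    ):
        return first
    # heterozygote: >=2 concordant replicates, <=2 alleles overall
    if len(alleles) <= 2:
        for pair, k in counts.items():
            if pair[0] != pair[1] and k >= 2:
                return pair
    return None


def call_sex(sry_flags) -> str:
    """Male iff any replicate amplified the Y-linked marker."""
    flags = list(sry_flags)
    if not flags:
        raise ValueError("need at least one sex-marker replicate flag")
    return MALE if any(flags) else FEMALE


@dataclass
class ConsensusGenotype:
    """Per-sample multilocus consensus with sex call and acceptance flag."""

    sample_id: str
    calls: dict[str, AllelePair | None]
    sex: str
    min_loci: int = 6
    pattern: dict[str, object] = field(default_factory=dict)

    @property
    def n_scored(self) -> int:
        return sum(1 for v in self.calls.values() if v is not None)

    @property
    def accepted(self) -> bool:
        return self.n_scored >= self.min_loci


def call_consensus_sample(
    sample_table: pd.DataFrame,
    loci: list[str],
    min_loci: int = 6,
    n_replicates: int = 3,
) -> ConsensusGenotype:
    """Consensus-call one sample's replicate table over a fixed locus panel.

    ``sample_table`` holds this sample's rows of the raw replicate table.
    Loci absent from the table count as entirely missing; unknown locus names
    in the table raise.
    """
    unknown = set(sample_table["locus"]) - set(loci)
    if unknown:
        raise ValueError(f"unknown loci in replicate table: {sorted(unknown)}")
    sample_id = str(sample_table["sample_id"].iloc[0])

    calls: dict[str, AllelePair | None] = {}
    for locus in loci:
        rows = sample_table[sample_table["locus"] == locus]
        slots: list[AllelePair | None] = [None] * n_replicates
        for _, row in rows.iterrows():
            r = int(row["replicate"]) - 1
            a1, a2 = row["allele1"], row["allele2"]
            if not (isinstance(a1, float) and math.isnan(a1)):
                slots[r] = (int(a1), int(a2))
        calls[locus] = call_consensus_locus(slots)

    if "sry_amplified" in sample_table.columns:
        per_rep = sample_table.groupby("replicate")["sry_amplified"].any()
        sex = call_sex(per_rep.tolist())
    else:
        sex = FEMALE
    return ConsensusGenotype(sample_id=sample_id, calls=calls, sex=sex, min_loci=min_loci)


def consensus_table(
    replicates: pd.DataFrame,
    loci: list[str] | None = None,
    min_loci: int = 6,
    n_replicates: int = 3,
    patterns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Consensus-call every sample of a raw replicate table.

    Returns one row per sample with per-locus ``"a1/a2"`` strings (empty for
    no call), ``n_scored``, ``accepted``, ``sex`` and sample metadata; optional
    qualitative pattern-locus classes are merged in from ``patterns``
    (indexed by ``sample_id``), never entering the consensus scoring.
    """
    if loci is None:
        loci = sorted(replicates["locus"].unique())
    meta_cols = [c for c in ("session", "day", "method") if c in replicates.columns]

    rows = []
    for sample_id, tab in replicates.groupby("sample_id", sort=True):
        cg = call_consensus_sample(tab, loci, min_loci=min_loci, n_replicates=n_replicates)
        row: dict = {"sample_id": sample_id}
        for c in meta_cols:
            row[c] = tab[c].iloc[0]
        for locus in loci:
            pair = cg.calls[locus]
            row[locus] = "" if pair is None else f"{pair[0]}/{pair[1]}"
        row["n_scored"] = cg.n_scored
        row["accepted"] = cg.accepted
        row["sex"] = cg.sex
        rows.append(row)
    out = pd.DataFrame(rows)
    if patterns is not None:
        out = out.merge(patterns, on="sample_id", how="left")
    return out


def _rate_with_se(per_sample: pd.Series) -> tuple[float, float]:
    vals = per_sample.to_numpy(dtype=float)
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se


def missing_rate(replicates: pd.DataFrame, group_by: str | None = None) -> pd.DataFrame:
    """Proportion of missing replicate-locus slots, mean +/- SE across samples.

    ``group_by`` is a column of the replicate table (``session``, ``locus``)
    or ``None`` for the overall rate.  The SE is the standard error of the
    per-sample missing proportions within each group.
    """
    if replicates.empty:
        raise ValueError("empty replicate table")
    df = replicates.copy()
    df["is_missing"] = df["allele1"].isna()

    def summarize(sub: pd.DataFrame) -> pd.Series:
        per_sample = sub.groupby("sample_id")["is_missing"].mean()
        _, se = _rate_with_se(per_sample)
        return pd.Series(
            {
                "rate": float(sub["is_missing"].mean()),
                "se": se,
                "n_samples": len(per_sample),
            }
        )

    if group_by is None:
        return summarize(df).to_frame().T
    out = df.groupby(group_by).apply(summarize, include_groups=False)
    return out.reset_index()


def false_homozygote_rate(
    replicates: pd.DataFrame,
    consensus: pd.DataFrame,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Share of homozygote replicates within consensus-heterozygote combos.

    Only sample/locus combinations whose consensus call is heterozygous
    qualify; within them, the numerator counts non-missing homozygous
    replicates (apparent allelic dropout) and the denominator all non-missing
    replicates.  Reported as mean +/- SE of per-sample proportions.
    """
    locus_cols = [
        c for c in consensus.columns
        if c in set(replicates["locus"].unique())
    ]
    het: set[tuple[str, str]] = set()
    for _, row in consensus.iterrows():
        for locus in locus_cols:
            call = row[locus]
            if isinstance(call, str) and "/" in call:
                a, b = call.split("/")
                if a != b:
                    het.add((row["sample_id"], locus))
    df = replicates[~replicates["allele1"].isna()].copy()
    mask = [
        (s, l) in het for s, l in zip(df["sample_id"], df["locus"])
    ]
    df = df[np.asarray(mask, dtype=bool)]
    if df.empty:
        return pd.DataFrame(columns=["rate", "se", "n_samples"])
    df["is_hom"] = df["allele1"] == df["allele2"]

    def summarize(sub: pd.DataFrame) -> pd.Series:
        per_sample = sub.groupby("sample_id")["is_hom"].mean()
        _, se = _rate_with_se(per_sample)
        return pd.Series(
            {
                "rate": float(sub["is_hom"].mean()),
                "se": se,
                "n_samples": len(per_sample),
            }
        )

    if group_by is None:
        return summarize(df).to_frame().T
    out = df.groupby(group_by).apply(summarize, include_groups=False)
    return out.reset_index()


def filtering_summary(n_genotyped: int, n_rejected: int) -> dict[str, float]:
    """Bookkeeping of consensus filtering: removal percentage and retained count."""
    if n_rejected > n_genotyped:
        raise ValueError("cannot reject more samples than were genotyped")
    return {
        "n_genotyped": n_genotyped,
        "n_rejected": n_rejected,
        "percent_removed": 100.0 * n_rejected / n_genotyped,
        "n_retained": n_genotyped - n_rejected,
    }
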