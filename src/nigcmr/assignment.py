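"""Species assignment of monitored genotypes against a labelled tissue panel.

Genotypes are expanded into an individuals x alleles count matrix (0/1/2
copies per allele column, missing loci mean-imputed), panel and query rows
are projected jointly by principal component analysis, and each query is
assigned the species of the nearest labelled-group centroid on the first two
axes.  This operationalises the visual reading of a PCA scatter; admixture
modelling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _parse_call(value) -> tuple[int, int] | None:
    if isinstance(value, tuple):
        return value
    if isinstance(value, str) and "/" in value:
        a, b = value.split("/")
        return (int(a), int(b))
    return None


def genotype_matrix(
    genotypes: pd.DataFrame, loci: list[str], impute: bool = True
) -> tuple[np.ndarray, list[tuple[str, int]], np.ndarray]:
    """Allele-count matrix (individuals x allele columns).

    Column order is (locus, allele) sorted; a homozygote contributes 2 in its
    allele's column, a heterozygote 1 and 1.  Missing loci are imputed with
    the column mean (switchable off, leaving NaN).  Individuals missing every
    locus are excluded.

    Returns ``(matrix, columns, kept_row_mask)``.
    """
    parsed = [
        {locus: _parse_call(row[locus]) for locus in loci}
        for _, row in genotypes.iterrows()
    ]
    keep = np.asarray([any(v is not None for v in g.values()) for g in parsed])
    parsed = [g for g, k in zip(parsed, keep) if k]

    columns: list[tuple[str, int]] = []
    for locus in loci:
        alleles = sorted(
            {a for g in parsed if g[locus] is not None for a in g[locus]}
        )
        columns += [(locus, a) for a in alleles]
    col_index = {col: i for i, col in enumerate(columns)}

    mat = np.full((len(parsed), len(columns)), np.nan)
    for i, g in enumerate(parsed):
        for locus in loci:
            pair = g[locus]
            if pair is None:
                continue
            for locus_allele in [(locus, pair[0]), (locus, pair[1])]:
                j = col_index[locus_allele]
                if np.isnan(mat[i, j]):
                    mat[i, j] = 0.0
            mat[i, col_index[(locus, pair[0])]] += 1
            mat[i, col_index[(locus, pair[1])]] += 1
            # other alleles of a typed locus are 0 copies
            for a in [a for (l, a) in columns if l == locus]:
                if np.isnan(mat[i, col_index[(locus, a)]]):
                    mat[i, col_index[(locus, a)]] = 0.0
    if impute:
        col_mean = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = np.take(col_mean, idx[1])
    return mat, columns, keep


@dataclass
class AssignmentResult:
    coords: pd.DataFrame            # id, label (panel species or query), PC1, PC2
    variance_explained: np.ndarray  # fraction per axis, nonincreasing
    centroids: pd.DataFrame         # species, PC1, PC2
    assignments: pd.DataFrame       # query id, assigned species, centroid distances


def pca_assign(
    panel: pd.DataFrame,
    queries: pd.DataFrame,
    loci: list[str],
    species_column: str = "species",
    id_column: str = "id",
    min_class_size: int = 5,
    n_axes: int = 2,
) -> AssignmentResult:
    """Joint PCA of panel + queries and nearest-centroid species assignment.

    The reference panel needs at least two species classes with
    ``min_class_size`` members each; centroids are computed from labelled
    rows only, on the first ``n_axes`` principal axes, and each query takes
    the species of the closest centroid (Euclidean distance).
    """
    labels = panel[species_column].astype(str)
    class_sizes = labels[labels.notna() & (labels != "NA")].value_counts()
    if (class_sizes >= min_class_size).sum() < 2:
        raise ValueError(
            "reference panel needs >=2 species classes with "
            f">={min_class_size} members (got {class_sizes.to_dict()})"
        )
    usable_species = class_sizes[class_sizes >= min_class_size].index.tolist()

    combined = pd.concat(
        [
            panel[[id_column] + loci].assign(_label=labels.values, _is_query=False),
            queries[[id_column] + loci].assign(_label="query", _is_query=True),
        ],
        ignore_index=True,
    )
    mat, _, keep = genotype_matrix(combined, loci)
    combined = combined[keep].reset_index(drop=True)

    centered = mat - mat.mean(axis=0)
    # PCA by singular value decomposition of the centred count matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(len(centered) - 1, 1)
    var_frac = var / var.sum()
    if np.sum(var > 1e-12) < n_axes:
        raise ValueError("fewer than two informative principal axes")
    scores = u[:, :n_axes] * s[:n_axes]

    coords = pd.DataFrame(
        {
            "id": combined[id_column],
            "label": combined["_label"],
            **{f"PC{k + 1}": scores[:, k] for k in range(n_axes)},
        }
    )

    cent_rows = []
    for sp in usable_species:
        sel = (combined["_label"] == sp).to_numpy()
        cent_rows.append({"species": sp, **{
            f"PC{k + 1}": float(scores[sel, k].mean()) for k in range(n_axes)
        }})
    centroids = pd.DataFrame(cent_rows)

    assign_rows = []
    qsel = combined["_is_query"].to_numpy()
    cmat = centroids[[f"PC{k + 1}" for k in range(n_axes)]].to_numpy()
    for i in np.where(qsel)[0]:
        dists = np.linalg.norm(cmat - scores[i, :n_axes], axis=1)
        row = {"id": combined[id_column].iloc[i]}
        row.update(
            {f"dist_{sp}": d for sp, d in zip(centroids["species"], dists)}
        )
        row["assigned"] = centroids["species"].iloc[int(np.argmin(dists))]
        assign_rows.append(row)

    return AssignmentResult(
        coords=coords,
        variance_explained=var_frac,
        centroids=centroids,
        assignments=pd.DataFrame(assign_rows),
    )
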