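"""Capture-history containers for robust-design mark-recapture.

A :class:`CaptureHistorySet` holds binary detections of identified genotypes
over primary sampling occasions (PSOs, e.g. one field session) subdivided into
secondary sampling occasions (SSOs, e.g. one sampling day).  The population is
assumed open between PSOs and closed within a PSO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPRING = "spring"
FALL = "fall"


@dataclass
class CaptureHistorySet:
    """Detections of ``n`` genotypes over a robust-design session calendar.

    Parameters
    ----------
    detections
        Boolean array of shape ``(n, n_pso, max_sso)``.  Entries beyond the
        SSO count of a PSO must be ``False``.
    groups
        Group label per genotype (sex: ``"F"`` or ``"M"``).
    seasons
        Season label per PSO (``"spring"`` or ``"fall"``).
    sso_counts
        Number of secondary occasions per PSO.
    ids
        Optional genotype/individual identifiers.
    """

    detections: np.ndarray
    groups: np.ndarray
    seasons: list[str]
    sso_counts: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=bool)
        self.groups = np.asarray(self.groups, dtype=object)
        self.sso_counts = np.asarray(self.sso_counts, dtype=int)
        n, n_pso, max_sso = self.detections.shape
        if len(self.seasons) != n_pso or len(self.sso_counts) != n_pso:
            raise ValueError("seasons/sso_counts length must equal number of PSOs")
        if self.groups.shape[0] != n:
            raise ValueError("one group label per genotype required")
        if np.any(self.sso_counts < 1):
            raise ValueError("every PSO needs at least one SSO")
        for t, k in enumerate(self.sso_counts):
            if self.detections[:, t, k:].any():
                raise ValueError(f"detections beyond SSO count in PSO {t}")
        if not self.ids:
            self.ids = [f"G{i:04d}" for i in range(n)]

    @property
    def n_genotypes(self) -> int:
        return self.detections.shape[0]

    @property
    def n_pso(self) -> int:
        return self.detections.shape[1]

    def detections_per_genotype(self) -> np.ndarray:
        """Total number of detections (SSO-level) per genotype."""
        return self.detections.sum(axis=(1, 2))

    def detected_in_pso(self) -> np.ndarray:
        """Boolean (n, n_pso) array: genotype detected at least once in PSO."""
        return self.detections.any(axis=2)

    def total_detections(self) -> int:
        return int(self.detections.sum())

    def subset(self, mask: np.ndarray) -> "CaptureHistorySet":
        mask = np.asarray(mask, dtype=bool)
        return CaptureHistorySet(
            detections=self.detections[mask],
            groups=self.groups[mask],
            seasons=list(self.seasons),
            sso_counts=self.sso_counts.copy(),
            ids=[i for i, m in zip(self.ids, mask) if m],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (genotype, PSO) history string."""
        rows = []
        for i, gid in enumerate(self.ids):
            for t in range(self.n_pso):
                k = self.sso_counts[t]
                hist = "".join("1" if d else "0" for d in self.detections[i, t, :k])
                rows.append(
                    {
                        "id": gid,
                        "group": self.groups[i],
                        "pso": t + 1,
                        "season": self.seasons[t],
                        "history": hist,
                    }
                )
        return pd.DataFrame(rows)


def write_inp(chs: CaptureHistorySet, path: str) -> None:
    """Write a MARK-style .inp encoding (history string, one group column per sex)."""
    sexes = ["F", "M"]
    with open(path, "w") as fh:
        for i in range(chs.n_genotypes):
            hist = "".join(
                "".join(
                    "1" if d else "0"
                    for d in chs.detections[i, t, : chs.sso_counts[t]]
                )
                for t in range(chs.n_pso)
            )
            cols = " ".join("1" if chs.groups[i] == s else "0" for s in sexes)
            fh.write(f"/* {chs.ids[i]} */ {hist} {cols};\n")
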