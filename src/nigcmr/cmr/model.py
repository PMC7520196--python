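"""Model specification and parameter layout for the robust-design fits.

A :class:`ModelSpec` assigns each parameter family a structure:

======================  ====================================================
family                  meaning (real scale)
======================  ====================================================
``phi``                 apparent survival per between-PSO interval
``gamma_dprime``        P(on-site -> temporary emigrant) per interval
``gamma_prime``         P(emigrant stays off-site) per interval
``p``                   capture probability per SSO (first capture in a PSO)
``c``                   recapture probability per SSO (within-PSO recapture)
``alpha``               P(a capture is assigned to the correct genotype)
``f0``                  number of on-site individuals undetected in a PSO
======================  ====================================================

Structures: ``constant`` (alias ``.``), ``by_sex``, ``by_season``,
``by_sex_season``, ``fixed:<value>``; additionally ``by_sso`` for ``p``/``c``
(one value per secondary occasion index, shared over PSOs and sexes) and
``equal_p`` for ``c`` (recaptures share the capture probabilities).
Probabilities live on the logit link, ``f0`` on the log link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..histories import CaptureHistorySet

FAMILIES = ("phi", "gamma_prime", "gamma_dprime", "p", "c", "alpha", "f0")
GROUPS = ("F", "M")

_ALIASES = {
    ".": "constant",
    "sex": "by_sex",
    "season": "by_season",
    "sex_season": "by_sex_season",
    "sso": "by_sso",
}


def _logit(x):
    x = np.clip(x, 1e-10, 1 - 1e-10)
    return np.log(x / (1 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class ModelSpec:
    """Per-family structure strings, e.g. ``ModelSpec(phi="by_sex", p="by_season")``."""

    phi: str = "constant"
    gamma_prime: str = "constant"
    gamma_dprime: str = "constant"
    p: str = "constant"
    c: str = "constant"
    alpha: str = "constant"
    f0: str = "constant"
    name: str = ""

    def __post_init__(self) -> None:
        for fam in FAMILIES:
            raw = getattr(self, fam).strip()
            value = _ALIASES.get(raw, raw)
            if value.startswith("fixed"):
                float(value.split(":", 1)[1])  # validate now
            else:
                allowed = {"constant", "by_sex", "by_season", "by_sex_season"}
                if fam in ("p", "c"):
                    allowed.add("by_sso")
                if fam == "c":
                    allowed.add("equal_p")
                if value not in allowed:
                    raise ValueError(f"invalid structure {raw!r} for family {fam}")
            setattr(self, fam, value)
        if not self.name:
            self.name = ", ".join(f"{f}({getattr(self, f)})" for f in FAMILIES)

    def structure(self, family: str) -> str:
        return getattr(self, family)


@dataclass
class _Family:
    name: str
    link: str                    # "logit" | "log"
    index: np.ndarray | None     # cell grid -> free-parameter offset, or None
    n_free: int
    offset: int                  # position in the packed vector
    fixed_value: float | None = None
    equal_p: bool = False


@dataclass
class ParamLayout:
    """Mapping between the packed link-scale vector and real-scale grids."""

    spec: ModelSpec
    families: dict[str, _Family]
    n_params: int
    n_pso: int
    n_intervals: int
    max_sso: int
    season_idx: np.ndarray       # per PSO: 0 spring, 1 fall (as observed)

    def unpack(self, params: np.ndarray) -> dict[str, np.ndarray]:
        """Real-scale grids: phi/gammas (n_intervals, 2); p/c (T, 2, max_sso);
        alpha, f0 (T, 2)."""
        params = np.asarray(params, float)
        out: dict[str, np.ndarray] = {}
        for name, fam in self.families.items():
            if fam.equal_p:
                out[name] = out["p"]
                continue
            if fam.fixed_value is not None:
                shape = self._grid_shape(name)
                out[name] = np.full(shape, fam.fixed_value)
                continue
            free = params[fam.offset : fam.offset + fam.n_free]
            real = _expit(free) if fam.link == "logit" else np.exp(free)
            out[name] = real[fam.index]
        return out

    def _grid_shape(self, name: str) -> tuple:
        if name in ("phi", "gamma_prime", "gamma_dprime"):
            return (self.n_intervals, 2)
        if name in ("p", "c"):
            return (self.n_pso, 2, self.max_sso)
        return (self.n_pso, 2)

    def pack_init(self, init_real: dict[str, float | np.ndarray]) -> np.ndarray:
        """Link-scale start vector from per-family real-scale init values."""
        x = np.zeros(self.n_params)
        for name, fam in self.families.items():
            if fam.n_free == 0:
                continue
            v = np.broadcast_to(np.asarray(init_real[name], float), (fam.n_free,))
            x[fam.offset : fam.offset + fam.n_free] = (
                _logit(v) if fam.link == "logit" else np.log(np.maximum(v, 1e-6))
            )
        return x


def _season_index(seasons: list[str]) -> np.ndarray:
    return np.asarray([0 if s == "spring" else 1 for s in seasons])


def build_layout(spec: ModelSpec, chs: CaptureHistorySet) -> ParamLayout:
    """Resolve a spec against a history set's calendar and groups.

    Cells are keyed over the groups actually present in the data; a sex with
    no genotypes contributes no free parameters (its grid entries alias the
    first present group and never enter the likelihood).
    """
    T = chs.n_pso
    n_int = max(T - 1, 1)
    max_sso = chs.detections.shape[2]
    sidx = _season_index(chs.seasons)
    present = sorted({GROUPS.index(g) for g in chs.groups}) or [0]

    def eff_group(g: int) -> int:
        return g if g in present else present[0]

    families: dict[str, _Family] = {}
    offset = 0
    for name in FAMILIES:
        struct = spec.structure(name)
        link = "log" if name == "f0" else "logit"
        if struct.startswith("fixed"):
            families[name] = _Family(name, link, None, 0, offset,
                                     fixed_value=float(struct.split(":", 1)[1]))
            continue
        if struct == "equal_p" and name == "c":
            families[name] = _Family(name, link, None, 0, offset, equal_p=True)
            continue

        if name in ("phi", "gamma_prime", "gamma_dprime"):
            # cell grid (n_intervals, 2); interval season = season of departure PSO
            keys = np.empty((n_int, 2), dtype=object)
            for t in range(n_int):
                for g in range(2):
                    keys[t, g] = _cell_key(struct, sidx[min(t, T - 1)], eff_group(g), None)
        elif name in ("p", "c"):
            keys = np.empty((T, 2, max_sso), dtype=object)
            for t in range(T):
                for g in range(2):
                    for j in range(max_sso):
                        keys[t, g, j] = _cell_key(struct, sidx[t], eff_group(g), j)
        else:  # alpha, f0
            keys = np.empty((T, 2), dtype=object)
            for t in range(T):
                for g in range(2):
                    keys[t, g] = _cell_key(struct, sidx[t], eff_group(g), None)

        uniq = sorted(set(keys.ravel().tolist()))
        lookup = {k: i for i, k in enumerate(uniq)}
        index = np.vectorize(lookup.get)(keys)
        families[name] = _Family(name, link, index, len(uniq), offset)
        offset += len(uniq)

    return ParamLayout(
        spec=spec,
        families=families,
        n_params=offset,
        n_pso=T,
        n_intervals=n_int,
        max_sso=max_sso,
        season_idx=sidx,
    )


def _cell_key(struct: str, season: int, group: int, sso: int | None):
    if struct == "constant":
        return ("all",)
    if struct == "by_sex":
        return ("g", group)
    if struct == "by_season":
        return ("s", season)
    if struct == "by_sex_season":
        return ("gs", group, season)
    if struct == "by_sso":
        return ("j", sso)
    raise AssertionError(struct)
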