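"""Composite likelihood of the robust design with misidentification.

The observed data are genotype detection histories.  Genotypes detected at
least twice study-wide cannot be ghosts (misidentification fabricates a
unique genotype per error, so a ghost appears exactly once); study-wide
singletons are a mixture of once-caught correctly identified animals and
ghosts.  The negative log-likelihood is the sum of two components sharing
one parameter set:

**Closed misidentification component, per (PSO t, sex g).**  On-site
individuals are modelled as a Poisson superpopulation with intensity
``Lambda = f0 / P0`` (``P0`` = probability an on-site animal yields no
recorded capture in the PSO, so ``f0`` keeps its usual meaning as the
expected number of on-site-but-undetected individuals).  Within the PSO an
animal's *recorded* history is a thinned capture process: a recorded capture
occurs per SSO with ``p * alpha`` before the first recorded capture and
``c * alpha`` after it (a capture happens with ``p`` or ``c``; it is
attributed to the right genotype with probability ``alpha``, otherwise it
spawns a ghost).  Poisson thinning makes the count of every observable
history class an independent Poisson variable:

- a known-real genotype with within-PSO history ``w`` contributes
  ``log(Lambda * sigma(w))``,
- a study-wide singleton recorded at SSO j of PSO t contributes the mixture
  cell ``log(Lambda * (sigma_1(j) * S_out(t) + G(j)))``: the real branch is
  the single-record within-PSO history ``sigma_1(j)`` times the open-model
  probability ``S_out(t)`` that a real animal on-site in t was never
  detected in any other PSO (this cross-session absence is what separates a
  once-caught animal from a ghost and identifies ``alpha``); the ghost
  branch ``G(j) = (1 - alpha) * (rho_j p_j + (1 - rho_j) c_j)`` is the
  expected ghost yield per on-site animal at SSO j, with ``rho_j`` the
  probability of no recorded capture before j,
- the normalising term is ``-Lambda * (p* + G_tot)`` with ``p* = 1 - P0``.

The behavioural first-capture/recapture switch keys on *recorded* captures
(fecal sampling has no physical trap response; the switch is a statistical
device, and keying it on recorded captures keeps the thinning exact).

**Open component.**  Each multi-detection genotype, conditional on its first
detection, follows a hidden three-state chain over PSOs (on-site, temporary
emigrant, dead) with survival ``phi`` and Markovian emigration
(on->off ``gamma''``, off stays off ``gamma'``); the emission for an
on-site animal is ``p*`` when detected in the PSO and ``P0`` when not, and
off-site or dead animals cannot be detected.  Evaluated by forward
recursion.  The before-t part of ``S_out`` conditions on presence since the
first PSO (the generator's closed-recruitment default).

Detection indicators after the first detection enter both components; the
product is a composite likelihood in the style of the usual robust-design
factorisation, not an exact joint density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..histories import CaptureHistorySet
from .model import GROUPS, ModelSpec, ParamLayout, build_layout

_EPS = 1e-12
_PENALTY = 1e10


@dataclass
class _ClosedCell:
    hists: np.ndarray      # (n_unique, k_t) bool, known-real within-PSO histories
    counts: np.ndarray     # (n_unique,) multiplicities
    singles: np.ndarray    # (k_t,) singleton records per SSO


class PreparedData:
    """Histories reorganised for repeated likelihood evaluation."""

    def __init__(self, chs: CaptureHistorySet):
        det = chs.detections
        totals = chs.detections_per_genotype()
        if np.any(totals == 0):
            raise ValueError("histories with zero detections are not allowed")
        unknown = set(chs.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {unknown}")
        self.chs = chs
        self.T = chs.n_pso
        self.k = chs.sso_counts
        gidx = np.asarray([GROUPS.index(g) for g in chs.groups])
        self.active_groups = sorted(set(gidx.tolist()))

        d_pso = chs.detected_in_pso()
        multi = totals >= 2
        self.n_multi = int(multi.sum())
        self.n_detections = chs.total_detections()

        # closed cells
        self.cells: dict[tuple[int, int], _ClosedCell] = {}
        for t in range(self.T):
            kt = self.k[t]
            for g in self.active_groups:
                sel = multi & d_pso[:, t] & (gidx == g)
                hists = det[sel, t, :kt]
                if len(hists):
                    hists, counts = np.unique(hists, axis=0, return_counts=True)
                else:
                    hists = np.zeros((0, kt), dtype=bool)
                    counts = np.zeros(0, dtype=int)
                singles = np.zeros(kt, dtype=int)
                sel1 = (~multi) & d_pso[:, t] & (gidx == g)
                for i in np.where(sel1)[0]:
                    j = int(np.argmax(det[i, t, :kt]))
                    singles[j] += 1
                self.cells[(t, g)] = _ClosedCell(hists, counts, singles)

        # open patterns (multi-detection genotypes only)
        pats = d_pso[multi]
        grps = gidx[multi]
        if len(pats):
            stacked = np.column_stack([grps[:, None], pats]).astype(np.int8)
            uniq, counts = np.unique(stacked, axis=0, return_counts=True)
            self.open_groups = uniq[:, 0].astype(int)
            self.open_patterns = uniq[:, 1:].astype(bool)
            self.open_counts = counts
            self.open_first = np.argmax(self.open_patterns, axis=1)
        else:
            self.open_groups = np.zeros(0, dtype=int)
            self.open_patterns = np.zeros((0, self.T), dtype=bool)
            self.open_counts = np.zeros(0, dtype=int)
            self.open_first = np.zeros(0, dtype=int)

        # open patterns regrouped per sex for vectorised forward recursion
        self.open_by_group: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for g in self.active_groups:
            sel = self.open_groups == g
            self.open_by_group[g] = (
                self.open_patterns[sel],
                self.open_counts[sel],
                self.open_first[sel],
            )

        # counts needed by derived quantities
        self.known_real_in_cell = {
            key: int(cell.counts.sum()) for key, cell in self.cells.items()
        }
        self.singletons_in_cell = {
            key: cell.singles.copy() for key, cell in self.cells.items()
        }


def _closed_cell_quantities(pj, cj, a):
    """Per-SSO closed-component building blocks for one (PSO, sex) cell."""
    ap = np.clip(pj * a, _EPS, 1 - _EPS)
    ac = np.clip(cj * a, _EPS, 1 - _EPS)
    log1m_ap = np.log1p(-ap)
    log1m_ac = np.log1p(-ac)
    # rho_j: P(no recorded capture before SSO j | on-site)
    rho = np.exp(np.concatenate([[0.0], np.cumsum(log1m_ap)[:-1]]))
    p0 = float(np.exp(np.sum(log1m_ap)))
    pstar = 1.0 - p0
    # sigma_1(j): single recorded capture exactly at j
    tail = np.exp(np.concatenate([np.cumsum(log1m_ac[::-1])[::-1][1:], [0.0]]))
    sigma1 = rho * ap * tail
    ghost = (1.0 - a) * (rho * pj + (1.0 - rho) * cj)
    return ap, ac, log1m_ap, log1m_ac, rho, p0, pstar, sigma1, ghost


def _log_sigma(hists: np.ndarray, ap, log1m_ap, ac, log1m_ac) -> np.ndarray:
    """log probability of recorded within-PSO histories (each with >=1 record)."""
    n, k = hists.shape
    first = np.argmax(hists, axis=1)
    cum0 = np.concatenate([[0.0], np.cumsum(log1m_ap)])
    w = hists.astype(float)
    per = w * np.log(ac) + (1.0 - w) * log1m_ac          # (n, k)
    cper = np.cumsum(per, axis=1)
    total = cper[:, -1]
    at_first = cper[np.arange(n), first]
    tail = total - at_first
    return cum0[first] + np.log(ap[first]) + tail


def _transition(phi: float, gd: float, gp: float) -> np.ndarray:
    """State order: on-site, temporary emigrant, dead."""
    return np.array(
        [
            [phi * (1 - gd), phi * gd, 1 - phi],
            [phi * (1 - gp), phi * gp, 1 - phi],
            [0.0, 0.0, 1.0],
        ]
    )


def _s_out(phi, gp, gd, p0_cache, g, T) -> np.ndarray:
    """Per-PSO never-detected-elsewhere probability for group g."""
    # backward: b[t, s] = P(no detection in PSOs > t | state s at t)
    b = np.ones((T, 3))
    for t in range(T - 2, -1, -1):
        m = _transition(phi[t, g], gd[t, g], gp[t, g])
        emit = np.array([p0_cache[t + 1, g], 1.0, 1.0])
        b[t] = m @ (emit * b[t + 1])
    # forward: f_nd[t, s] = P(no detection in PSOs < t, state s at t | entry at 0)
    # f_any[t, s] = P(state s at t | entry at 0)
    f_nd = np.zeros((T, 3))
    f_any = np.zeros((T, 3))
    f_nd[0] = f_any[0] = np.array([1.0, 0.0, 0.0])
    for t in range(1, T):
        m = _transition(phi[t - 1, g], gd[t - 1, g], gp[t - 1, g])
        emit = np.array([p0_cache[t - 1, g], 1.0, 1.0])
        f_nd[t] = (f_nd[t - 1] * emit) @ m
        f_any[t] = f_any[t - 1] @ m
    s_before = np.where(f_any[:, 0] > _EPS, f_nd[:, 0] / np.maximum(f_any[:, 0], _EPS), 1.0)
    return np.clip(s_before, 0.0, 1.0) * b[:, 0]


def negloglik_prepared(params: np.ndarray, layout: ParamLayout, prep: PreparedData) -> float:
    """Negative composite log-likelihood for a packed link-scale vector."""
    grids = layout.unpack(params)
    phi, gp, gd = grids["phi"], grids["gamma_prime"], grids["gamma_dprime"]
    p, c, alpha, f0 = grids["p"], grids["c"], grids["alpha"], grids["f0"]

    T = prep.T
    cellq: dict[tuple[int, int], tuple] = {}
    pstar_cache = np.zeros((T, 2))
    p0_cache = np.ones((T, 2))
    for t in range(T):
        kt = prep.k[t]
        for g in prep.active_groups:
            q = _closed_cell_quantities(p[t, g, :kt], c[t, g, :kt], float(alpha[t, g]))
            cellq[(t, g)] = q
            p0_cache[t, g] = q[5]
            pstar_cache[t, g] = q[6]

    ll = 0.0
    for g in prep.active_groups:
        s_out = _s_out(phi, gp, gd, p0_cache, g, T)
        for t in range(T):
            ap, ac, l1ap, l1ac, rho, p0, pstar, sigma1, ghost = cellq[(t, g)]
            lam = float(f0[t, g]) / max(p0, _EPS)
            cell = prep.cells[(t, g)]
            if cell.counts.sum() + cell.singles.sum():
                loglam = np.log(max(lam, _EPS))
                if len(cell.counts):
                    ls = _log_sigma(cell.hists, ap, l1ap, ac, l1ac)
                    ll += float(np.dot(cell.counts, loglam + ls))
                nz = cell.singles > 0
                if nz.any():
                    mix = np.clip(sigma1 * s_out[t] + ghost, _EPS, None)
                    ll += float(np.dot(cell.singles[nz], loglam + np.log(mix[nz])))
            ll -= lam * (pstar + ghost.sum())

    # open component, vectorised over detection patterns within each sex
    for g in prep.active_groups:
        pats, counts, firsts = prep.open_by_group[g]
        if not len(pats):
            continue
        v = np.zeros((len(pats), 3))
        v[:, 0] = 1.0
        for t in range(1, T):
            started = firsts < t
            if not started.any():
                continue
            m = _transition(phi[t - 1, g], gd[t - 1, g], gp[t - 1, g])
            v[started] = v[started] @ m
            det_t = started & pats[:, t]
            nod_t = started & ~pats[:, t]
            v[det_t] *= np.array([pstar_cache[t, g], 0.0, 0.0])
            v[nod_t] *= np.array([p0_cache[t, g], 1.0, 1.0])
        totals = v.sum(axis=1)
        if np.any(totals <= 0):
            return _PENALTY
        ll += float(np.dot(counts, np.log(totals)))

    if not np.isfinite(ll):
        return _PENALTY
    return -ll


def singleton_real_posterior(
    grids: dict[str, np.ndarray], prep: PreparedData, t: int, g: int
) -> np.ndarray:
    """P(real | study-wide singleton at SSO j of PSO t, sex g) under ``grids``."""
    kt = prep.k[t]
    p0_cache = np.ones((prep.T, 2))
    for u in range(prep.T):
        ku = prep.k[u]
        for gg in prep.active_groups:
            ap = np.clip(
                grids["p"][u, gg, :ku] * float(grids["alpha"][u, gg]), _EPS, 1 - _EPS
            )
            p0_cache[u, gg] = float(np.prod(1 - ap))
    *_, sigma1, ghost = _closed_cell_quantities(
        grids["p"][t, g, :kt], grids["c"][t, g, :kt], float(grids["alpha"][t, g])
    )
    s_out = _s_out(
        grids["phi"], grids["gamma_prime"], grids["gamma_dprime"], p0_cache, g, prep.T
    )
    real = sigma1 * s_out[t]
    return real / np.clip(real + ghost, _EPS, None)


def negloglik(spec: ModelSpec, params: np.ndarray, chs: CaptureHistorySet) -> float:
    """Convenience wrapper preparing the data on every call (tests, one-offs)."""
    layout = build_layout(spec, chs)
    return negloglik_prepared(np.asarray(params, float), layout, PreparedData(chs))


def forward_state_probabilities(
    layout: ParamLayout, params: np.ndarray, prep: PreparedData, pattern_index: int
) -> np.ndarray:
    """Normalised forward state probabilities for one open-component pattern.

    Returns an array (n_pso, 3) with rows summing to 1 from the pattern's
    first detection onward (and NaN before it); diagnostic companion to the
    forward recursion used in the likelihood.
    """
    grids = layout.unpack(params)
    phi, gp, gd = grids["phi"], grids["gamma_prime"], grids["gamma_dprime"]
    p, alpha = grids["p"], grids["alpha"]
    T = prep.T
    pat = prep.open_patterns[pattern_index]
    g = prep.open_groups[pattern_index]
    e = prep.open_first[pattern_index]

    out = np.full((T, 3), np.nan)
    v = np.array([1.0, 0.0, 0.0])
    out[e] = v
    for t in range(e + 1, T):
        m = _transition(phi[t - 1, g], gd[t - 1, g], gp[t - 1, g])
        v = v @ m
        kt = prep.k[t]
        ap = np.clip(p[t, g, :kt] * alpha[t, g], _EPS, 1 - _EPS)
        p0 = float(np.prod(1 - ap))
        emit = np.array([1 - p0, 0.0, 0.0]) if pat[t] else np.array([p0, 1.0, 1.0])
        v = v * emit
        v = v / v.sum()
        out[t] = v
    return out
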