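"""Fictive-longitudinal population correspondence via the earth mover's
distance.

Chronic recordings cannot follow the same neurons before and after a
recovery treatment, so correspondence between the "before" (post-LTMD) and
"after" (post-recovery) cross-sectional populations is reconstructed
fictively: each neuron is a point in the 2-D response plane (peak grating
response x noise F1 response), the two clouds are given uniform mass, and
the optimal-transport plan of minimum total Euclidean cost (the earth
mover's distance) defines a flow field of putative response changes.
Summed flow components along one response axis, binned over the plane,
give the heat maps whose above/below-diagonal asymmetry distinguishes
stimulus-specific recovery; a chi-square contrast on positive-flow mass
above vs below the diagonal compares two recovery conditions.

Axes are scaled by the pooled 95th percentile of each response before
transport so the two response ranges contribute comparably to the ground
distance; flows are reported in the original spikes/s units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

__all__ = [
    "CorrespondenceResult",
    "FlowHeatmap",
    "axis_scales",
    "select_top_responsive",
    "earth_mover_correspondence",
    "flow_heatmap",
    "diagonal_flow_contrast",
]

GRATING_COL = "grating_resp"
NOISE_COL = "noise_f1"


@dataclass
class CorrespondenceResult:
    """Optimal-transport plan between two population point clouds.

    ``flows`` columns: ``x0, y0, x1, y1, mass`` with (x, y) = (grating
    response, noise F1) in spikes/s; source and target masses each sum
    to 1.  ``total_cost`` is the mass-weighted mean transport distance in
    scaled units (Rubner normalization); ``scaling`` holds the per-axis
    divisors applied before solving.
    """

    flows: pd.DataFrame
    total_cost: float
    scaling: tuple[float, float]


@dataclass
class FlowHeatmap:
    """Flow components along one response axis, binned at the flow source
    over the scaled [0, 1]^2 plane.  Values are signed sums of
    mass x displacement, spikes/s."""

    grid: np.ndarray
    axis: str                    # "grating" | "noise"
    x_edges: np.ndarray          # grating axis, scaled units
    y_edges: np.ndarray          # noise axis, scaled units
    scaling: tuple[float, float]
    n_units: int = 0             # source-cloud size behind the flows


def axis_scales(*samples: pd.DataFrame, percentile: float = 95.0
                ) -> tuple[float, float]:
    """Per-axis scale factors: the pooled ``percentile`` of each response
    across all provided samples (floored at a small positive value)."""
    pooled = pd.concat(samples, ignore_index=True)
    s_g = float(np.percentile(pooled[GRATING_COL], percentile))
    s_n = float(np.percentile(pooled[NOISE_COL], percentile))
    return max(s_g, 1e-9), max(s_n, 1e-9)


def select_top_responsive(sample: pd.DataFrame, n: int = 500,
                          scales: tuple[float, float] | None = None
                          ) -> pd.DataFrame:
    """The ``n`` most responsive units of a population sample.

    Ranking score is ``max(grating_resp / s_g, noise_f1 / s_n)`` so a unit
    strongly driven by either stimulus qualifies; ties broken by unit_id
    for determinism.  If the sample is smaller than ``n`` all units are
    used (with a warning).
    """
    if len(sample) < n:
        warnings.warn(f"sample has {len(sample)} units, fewer than the "
                      f"requested {n}; using all")
        n = len(sample)
    if scales is None:
        scales = axis_scales(sample)
    s_g, s_n = scales
    score = np.maximum(sample[GRATING_COL] / s_g, sample[NOISE_COL] / s_n)
    out = sample.assign(_score=score).sort_values(
        ["_score", "unit_id"], ascending=[False, True], kind="mergesort")
    return out.head(n).drop(columns="_score").reset_index(drop=True)


def _transport_plan_lp(dist: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Exact transport plan for unequal marginals via the HiGHS LP solver."""
    n, m = dist.shape
    # flatten plan row-major; equality constraints on both marginals
    a_eq_rows = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq_rows[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_eq_rows[n + j, j::m] = 1.0
    res = linprog(dist.ravel(), A_eq=a_eq_rows,
                  b_eq=np.concatenate([a, b]),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return res.x.reshape(n, m)


def earth_mover_correspondence(sample_a: pd.DataFrame,
                               sample_b: pd.DataFrame,
                               scales: tuple[float, float] | None = None
                               ) -> CorrespondenceResult:
    """Minimum-cost transport between two populations in response space.

    Uniform masses 1/|A| and 1/|B|; Euclidean ground distance in the
    scaled plane.  Equal-size problems are solved as an exact assignment
    (each source unit maps to one target unit); unequal sizes fall back to
    the exact transport linear program, where mass may split.
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("both samples must be nonempty")
    if scales is None:
        scales = axis_scales(sample_a, sample_b)
    s_g, s_n = scales

    pa = sample_a[[GRATING_COL, NOISE_COL]].to_numpy(dtype=float)
    pb = sample_b[[GRATING_COL, NOISE_COL]].to_numpy(dtype=float)
    qa = pa / np.array([s_g, s_n])
    qb = pb / np.array([s_g, s_n])
    dist = cdist(qa, qb)

    n, m = len(qa), len(qb)
    if n == m:
        rows, cols = linear_sum_assignment(dist)
        mass = np.full(n, 1.0 / n)
        flows = pd.DataFrame({
            "x0": pa[rows, 0], "y0": pa[rows, 1],
            "x1": pb[cols, 0], "y1": pb[cols, 1],
            "mass": mass,
        })
        total_cost = float((dist[rows, cols] * mass).sum())
    else:
        a = np.full(n, 1.0 / n)
        b = np.full(m, 1.0 / m)
        plan = _transport_plan_lp(dist, a, b)
        src, dst = np.nonzero(plan > 1e-12)
        flows = pd.DataFrame({
            "x0": pa[src, 0], "y0": pa[src, 1],
            "x1": pb[dst, 0], "y1": pb[dst, 1],
            "mass": plan[src, dst],
        })
        total_cost = float((plan * dist).sum())
    return CorrespondenceResult(flows=flows, total_cost=total_cost,
                                scaling=(s_g, s_n))


def flow_heatmap(corr: CorrespondenceResult, axis: str = "noise",
                 bins: int = 25) -> FlowHeatmap:
    """Bin flows at their source points; each bin accumulates the summed
    mass-weighted displacement along the chosen axis (spikes/s).

    The grid covers the scaled [0, 1]^2 plane; sources outside are clamped
    to the edge bins.
    """
    if axis not in ("grating", "noise"):
        raise ValueError("axis must be 'grating' or 'noise'")
    s_g, s_n = corr.scaling
    f = corr.flows
    x = f["x0"].to_numpy() / s_g
    y = f["y0"].to_numpy() / s_n
    comp = (f["x1"] - f["x0"] if axis == "grating"
            else f["y1"] - f["y0"]).to_numpy()
    w = f["mass"].to_numpy() * comp

    edges = np.linspace(0.0, 1.0, bins + 1)
    ix = np.clip(np.digitize(x, edges) - 1, 0, bins - 1)
    iy = np.clip(np.digitize(y, edges) - 1, 0, bins - 1)
    grid = np.zeros((bins, bins))
    np.add.at(grid, (iy, ix), w)
    n_units = int(len(np.unique(f[["x0", "y0"]].to_numpy(), axis=0)))
    return FlowHeatmap(grid=grid, axis=axis, x_edges=edges, y_edges=edges,
                       scaling=corr.scaling, n_units=n_units)


def _positive_flow_by_diagonal(hm: FlowHeatmap) -> tuple[float, float]:
    """Positive-flow magnitude above and below the unit diagonal of the
    scaled plane (above: scaled noise response exceeds scaled grating
    response)."""
    xc = 0.5 * (hm.x_edges[:-1] + hm.x_edges[1:])
    yc = 0.5 * (hm.y_edges[:-1] + hm.y_edges[1:])
    above = yc[:, None] > xc[None, :]
    pos = np.clip(hm.grid, 0.0, None)
    return float(pos[above].sum()), float(pos[~above].sum())


def diagonal_flow_contrast(hm_x: FlowHeatmap, hm_y: FlowHeatmap
                           ) -> tuple[float, float]:
    """Chi-square contrast of positive-flow mass above vs below the
    diagonal between two conditions.

    Builds the 2x2 table {above, below diagonal} x {condition X, condition
    Y} of positive-flow magnitudes and tests homogeneity against the null
    that flow is equal in the two conditions: the expected value of each
    cell is half its diagonal-side total, so both a difference in total
    positive flow (stimulus-specific recovery magnitude) and a shift of
    flow across the diagonal contribute to the statistic (df = 2).
    Because heat-map values are mass-normalized (masses sum to 1), entries
    are rescaled by each flow field's source-cloud size, giving per-neuron
    displacement sums in spikes/s on a count-like scale.
    """
    if hm_x.grid.shape != hm_y.grid.shape:
        raise ValueError("heat maps must share the same grid")
    table = np.array([
        np.asarray(_positive_flow_by_diagonal(hm_x)) * max(hm_x.n_units, 1),
        np.asarray(_positive_flow_by_diagonal(hm_y)) * max(hm_y.n_units, 1),
    ])
    side_totals = table.sum(axis=0)
    if table.sum() == 0 or (side_totals == 0).any() \
            or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin of the "
                         "positive-flow table is zero")
    expected = np.vstack([side_totals / 2.0, side_totals / 2.0])
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, p
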