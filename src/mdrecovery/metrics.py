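"""Per-unit response metrics for grating and noise protocols.

Implements the single-unit analysis chain: spontaneous rate from blank
trials; baseline-subtracted evoked responses; vector-sum preferred
orientation (half the complex phase of sum F(theta) e^{2 i theta});
double-Gaussian orientation-tuning fit with derived OSI and half-width at
half-maximum; binocular orientation mismatch on the 180-degree cycle;
difference-of-Gaussians spatial-frequency fit; ocular dominance index
(contra - ipsi)/(contra + ipsi); F1 amplitude of the cycle-averaged
response to the contrast-modulated noise; a contrast-response curve with
its half-maximum contrast C_1/2; and the broad/narrow waveform classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TuningFit",
    "SFFit",
    "UndefinedMetricError",
    "spontaneous_rate",
    "evoked_response",
    "condition_responses",
    "preferred_orientation",
    "fit_orientation_tuning",
    "osi",
    "tuning_width",
    "orientation_difference",
    "fit_sf_tuning",
    "odi_unit",
    "select_responsive_grating",
    "f1_response",
    "contrast_response",
    "classify_waveform",
    "compute_unit_metrics",
    "RESPONSIVE_GRATING_SP_S",
    "RESPONSIVE_NOISE_F1",
]

RESPONSIVE_GRATING_SP_S = 2.0   # peak evoked rate threshold, either eye
RESPONSIVE_NOISE_F1 = 0.2       # F1 threshold, either eye
SIGMA_MIN_DEG = 3.0             # lower bound on fitted tuning width
SIGMA_MAX_DEG = 90.0


class UndefinedMetricError(ValueError):
    """A metric is undefined for this unit (e.g. zero resultant vector,
    zero total response, missing blank trials); such units are excluded
    from the corresponding population summaries."""


@dataclass
class TuningFit:
    """Double-Gaussian orientation tuning fit.

    Model: B + A1 g(theta; theta_pref, sigma) + A2 g(theta;
    theta_pref + 180, sigma) over the full 360-degree direction domain,
    with circularly wrapped Gaussians of shared width sigma.  R_pref and
    R_ortho are the fitted curve evaluated at the preferred and orthogonal
    orientations (negative fitted values clipped to zero for the OSI
    ratio).
    """

    theta_pref_deg: float
    A1: float
    A2: float
    sigma_deg: float
    B: float
    R_pref: float
    R_ortho: float
    osi: float
    hwhm_deg: float
    converged: bool
    rss: float

    def predict(self, theta_deg) -> np.ndarray:
        return _tuning_model(np.asarray(theta_deg, dtype=float),
                             self.theta_pref_deg, self.A1, self.A2,
                             self.sigma_deg, self.B)


@dataclass
class SFFit:
    """Difference-of-Gaussians spatial-frequency fit (linear SF axis)."""

    amp_center: float
    sigma_center: float
    amp_surround: float
    sigma_surround: float
    sf_pref_cpd: float
    converged: bool
    rss: float

    def predict(self, sf_cpd) -> np.ndarray:
        sf = np.asarray(sf_cpd, dtype=float)
        return (self.amp_center * np.exp(-0.5 * (sf / self.sigma_center) ** 2)
                - self.amp_surround
                * np.exp(-0.5 * (sf / self.sigma_surround) ** 2))


# ---------------------------------------------------------------------------
# Rates from trial tables

def spontaneous_rate(trials: pd.DataFrame, unit_id) -> float:
    """Mean rate over all blank-condition presentations of one unit."""
    rows = trials[(trials["unit_id"] == unit_id) & trials["is_blank"]]
    if len(rows) == 0:
        raise UndefinedMetricError(
            f"unit {unit_id} has no blank trials; spontaneous rate "
            "cannot be estimated")
    return float((rows["spike_count"] / rows["duration_s"]).mean())


def evoked_response(trials: pd.DataFrame, unit_id, eye: str,
                    direction_deg: float, sf_cpd: float,
                    spont: float | None = None) -> float:
    """Mean rate over repeats of one condition minus the spontaneous rate.

    Negative values (suppression below baseline) are preserved.
    """
    if spont is None:
        spont = spontaneous_rate(trials, unit_id)
    rows = trials[(trials["unit_id"] == unit_id)
                  & (trials["eye"] == eye)
                  & ~trials["is_blank"]
                  & np.isclose(trials["direction_deg"], direction_deg)
                  & np.isclose(trials["sf_cpd"], sf_cpd)]
    if len(rows) == 0:
        raise ValueError(
            f"no trials for unit {unit_id}, eye {eye}, direction "
            f"{direction_deg}, SF {sf_cpd}")
    return float((rows["spike_count"] / rows["duration_s"]).mean()) - spont


def condition_responses(trials: pd.DataFrame, unit_id, eye: str,
                        spont: float | None = None) -> pd.DataFrame:
    """Baseline-subtracted mean response for every nonblank (direction, SF)
    condition of one unit and eye.  Columns: ``direction_deg, sf_cpd,
    response`` (sp/s)."""
    if spont is None:
        spont = spontaneous_rate(trials, unit_id)
    rows = trials[(trials["unit_id"] == unit_id)
                  & (trials["eye"] == eye) & ~trials["is_blank"]]
    if len(rows) == 0:
        raise ValueError(f"no nonblank trials for unit {unit_id}, eye {eye}")
    rate = rows["spike_count"] / rows["duration_s"]
    out = (rate.groupby([rows["direction_deg"], rows["sf_cpd"]])
           .mean().rename("response").reset_index())
    out["response"] -= spont
    return out


# ---------------------------------------------------------------------------
# Orientation tuning

def preferred_orientation(directions_deg, responses) -> float:
    """Vector-sum preferred orientation, degrees in [0, 180).

    Half the complex phase of sum_theta F(theta) e^{2 i theta}, with
    F(theta) the response (averaged across spatial frequencies) at each
    stimulus direction.  A vanishing resultant (perfectly balanced
    responses) leaves the preference undefined.
    """
    theta = np.deg2rad(np.asarray(directions_deg, dtype=float))
    f = np.asarray(responses, dtype=float)
    if theta.size < 2:
        raise ValueError("need at least two distinct directions")
    resultant = np.sum(f * np.exp(2j * theta))
    scale = np.sum(np.abs(f))
    if scale == 0 or np.abs(resultant) < 1e-12 * max(scale, 1.0):
        raise UndefinedMetricError(
            "orientation preference undefined: resultant vector is zero")
    return float(np.mod(np.rad2deg(np.angle(resultant)) / 2.0, 180.0))


def _wrapped_gaussian(delta_deg, sigma):
    total = np.zeros_like(np.asarray(delta_deg, dtype=float))
    for k in (-360.0, 0.0, 360.0):
        total += np.exp(-0.5 * ((delta_deg + k) / sigma) ** 2)
    return total


def _tuning_model(theta, theta_pref, a1, a2, sigma, b):
    d1 = np.mod(theta - theta_pref + 180.0, 360.0) - 180.0
    d2 = np.mod(theta - theta_pref, 360.0) - 180.0   # distance from pref+180
    return (b + a1 * _wrapped_gaussian(d1, sigma)
            + a2 * _wrapped_gaussian(d2, sigma))


def fit_orientation_tuning(directions_deg, responses,
                           theta_pref_deg: float) -> TuningFit:
    """Fit the double-Gaussian tuning curve with the preference fixed.

    The preferred orientation comes from :func:`preferred_orientation` and
    is *not* refit; only amplitudes A1 >= 0, A2 >= 0, shared width sigma
    and baseline B are free.  Bounded least squares, multi-started over
    sigma in {10, 20, 40} degrees; the lowest-residual solution wins.
    The preferred-direction lobe (amplitude A1) is whichever of theta_pref
    / theta_pref + 180 fits larger, relabeled so A1 >= A2.
    """
    theta = np.asarray(directions_deg, dtype=float)
    f = np.asarray(responses, dtype=float)
    if theta.size != f.size or theta.size < 4:
        raise ValueError("need matched direction/response arrays, >= 4 points")

    fmax = float(f.max())
    amp0 = max(fmax - float(f.min()), 1e-6)
    lower = [0.0, 0.0, SIGMA_MIN_DEG, min(float(f.min()), 0.0) - 1.0]
    upper = [np.inf, np.inf, SIGMA_MAX_DEG, max(fmax, 0.0) + 1.0]

    def residual(p):
        return _tuning_model(theta, theta_pref_deg, *p) - f

    best = None
    for sigma0 in (10.0, 20.0, 40.0):
        p0 = [amp0, 0.5 * amp0, sigma0, max(min(float(f.min()), fmax), 0.0)]
        p0 = np.clip(p0, lower, upper)
        try:
            sol = least_squares(residual, p0, bounds=(lower, upper))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return TuningFit(theta_pref_deg, 0.0, 0.0, SIGMA_MIN_DEG, 0.0,
                         0.0, 0.0, np.nan, np.nan, False, np.inf)

    a1, a2, sigma, b = best.x
    pref = theta_pref_deg
    if a2 > a1:  # dominant lobe defines the preferred direction
        a1, a2 = a2, a1
        pref = np.mod(theta_pref_deg + 180.0, 360.0)

    r_pref = float(_tuning_model(np.array([pref]), pref, a1, a2, sigma, b)[0])
    ortho = np.array([pref - 90.0, pref + 90.0])
    r_ortho = float(np.mean(_tuning_model(ortho, pref, a1, a2, sigma, b)))
    r_pref_c, r_ortho_c = max(r_pref, 0.0), max(r_ortho, 0.0)
    osi_val = (np.nan if r_pref_c + r_ortho_c == 0
               else (r_pref_c - r_ortho_c) / (r_pref_c + r_ortho_c))

    fit = TuningFit(theta_pref_deg=float(np.mod(pref, 360.0)), A1=float(a1),
                    A2=float(a2), sigma_deg=float(sigma), B=float(b),
                    R_pref=r_pref, R_ortho=r_ortho, osi=float(osi_val),
                    hwhm_deg=np.nan, converged=bool(best.success),
                    rss=float(2.0 * best.cost))
    fit.hwhm_deg = tuning_width(fit) if a1 > 0 else np.nan
    return fit


def osi(fit: TuningFit) -> float:
    """Orientation selectivity index (R_pref - R_ortho)/(R_pref + R_ortho),
    from the fitted responses with negatives clipped to zero."""
    r_p, r_o = max(fit.R_pref, 0.0), max(fit.R_ortho, 0.0)
    if r_p + r_o <= 0:
        raise UndefinedMetricError("OSI undefined: zero total response")
    return (r_p - r_o) / (r_p + r_o)


def tuning_width(fit: TuningFit, grid_step_deg: float = 0.01) -> float:
    """Half-width at half-maximum of the fit above the baseline.

    Scanned outward from the peak of the dominant lobe on a fine grid; for
    an isolated Gaussian this equals sigma * sqrt(2 ln 2).
    """
    if fit.A1 <= 0:
        raise UndefinedMetricError("tuning width undefined: A1 = 0")
    offsets = np.arange(0.0, 90.0 + grid_step_deg, grid_step_deg)
    curve = fit.predict(fit.theta_pref_deg + offsets) - fit.B
    peak = curve[0]
    half = peak / 2.0
    below = np.nonzero(curve < half)[0]
    if below.size == 0:
        return 90.0  # never falls to half within the quarter cycle
    i = below[0]
    # linear interpolation between the straddling grid points
    x0, x1 = offsets[i - 1], offsets[i]
    y0, y1 = curve[i - 1], curve[i]
    return float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))


def orientation_difference(theta_contra_deg: float,
                           theta_ipsi_deg: float) -> float:
    """Contra minus ipsi preferred orientation along the 180-degree cycle,
    wrapped into (-90, 90]."""
    d = np.mod(theta_contra_deg - theta_ipsi_deg + 90.0, 180.0) - 90.0
    if d == -90.0:
        d = 90.0
    return float(d)


# ---------------------------------------------------------------------------
# Spatial-frequency tuning

def fit_sf_tuning(sf_cpd, responses) -> SFFit:
    """Difference-of-Gaussians fit of the SF tuning curve at the preferred
    orientation; the preferred SF is the argmax of the fitted curve on a
    fine grid up to twice the highest tested frequency.

    On non-convergence the raw argmax is used and the fit flagged.
    """
    sf = np.asarray(sf_cpd, dtype=float)
    f = np.asarray(responses, dtype=float)
    if sf.size < 4:
        raise ValueError("need at least 4 spatial-frequency conditions")
    order = np.argsort(sf)
    sf, f = sf[order], f[order]
    sf_hi = 2.0 * sf.max()

    amp0 = max(float(f.max()), 1e-6)
    lower = [0.0, 1e-4, 0.0, 1e-4]
    upper = [np.inf, 10.0 * sf.max(), np.inf, 10.0 * sf.max()]

    def model(p, x):
        ac, sc, asur, ssur = p
        return (ac * np.exp(-0.5 * (x / sc) ** 2)
                - asur * np.exp(-0.5 * (x / ssur) ** 2))

    best = None
    peak_sf = max(float(sf[np.argmax(f)]), sf.min())
    for sc0, ssur0 in ((peak_sf * 2, peak_sf * 0.5),
                       (sf.max(), sf.min()),
                       (peak_sf * 4, peak_sf)):
        p0 = np.clip([amp0 * 1.5, sc0, amp0 * 0.5, ssur0], lower, upper)
        try:
            sol = least_squares(lambda p: model(p, sf) - f, p0,
                                bounds=(lower, upper))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    grid = np.linspace(0.0, sf_hi, 2001)
    if best is not None and best.success:
        ac, sc, asur, ssur = best.x
        fit_curve = model(best.x, grid)
        sf_pref = float(grid[np.argmax(fit_curve)])
        return SFFit(float(ac), float(sc), float(asur), float(ssur),
                     sf_pref, True, float(2.0 * best.cost))
    # fallback: raw argmax, flagged as not converged
    return SFFit(amp0, peak_sf, 0.0, peak_sf, float(sf[np.argmax(f)]),
                 False, np.inf)


# ---------------------------------------------------------------------------
# Ocular dominance

def odi_unit(resp_contra: float, resp_ipsi: float) -> float:
    """Unit ocular dominance index (contra - ipsi)/(contra + ipsi).

    Negative evoked responses are clipped to zero before the ratio;
    +1 means purely contra (deprived eye in deprivation groups) dominated.
    """
    c, i = max(resp_contra, 0.0), max(resp_ipsi, 0.0)
    if c + i == 0:
        raise UndefinedMetricError("ODI undefined: both responses are zero")
    return (c - i) / (c + i)


def select_responsive_grating(metrics: pd.DataFrame,
                              threshold: float = RESPONSIVE_GRATING_SP_S
                              ) -> pd.DataFrame:
    """Units whose peak evoked grating response reaches ``threshold``
    (default 2.0 sp/s) through either eye."""
    keep = ((metrics["peak_grating_resp_contra"] >= threshold)
            | (metrics["peak_grating_resp_ipsi"] >= threshold))
    return metrics[keep]


# ---------------------------------------------------------------------------
# Noise-movie responses

def f1_response(counts, bin_s: float, period_s: float = 10.0) -> float:
    """Response amplitude at the contrast-modulation frequency (F1).

    Counts are folded into one modulation cycle; the cycle-averaged rate
    r(phi) over the m phase bins gives F1 = 2 |sum_k r_k e^{-2 pi i k/m}| / m
    in spikes/s.  Requires an integer number of bins per period and at
    least two full cycles.
    """
    counts = np.asarray(counts, dtype=float)
    m_float = period_s / bin_s
    m = int(round(m_float))
    if abs(m_float - m) > 1e-9 or m < 2:
        raise ValueError(
            f"bin width {bin_s}s does not divide the period {period_s}s "
            "into an integer number of bins")
    n_cycles = counts.size // m
    if n_cycles < 2:
        raise ValueError("recording must span at least two full periods")
    folded = counts[:n_cycles * m].reshape(n_cycles, m).mean(axis=0) / bin_s
    k = np.arange(m)
    return float(2.0 * np.abs(np.sum(folded * np.exp(-2j * np.pi * k / m)))
                 / m)


def cycle_average_spectrum(counts, bin_s: float, period_s: float = 10.0):
    """Frequencies (Hz) and single-sided amplitudes of the cycle-averaged
    rate; the F1 is the amplitude at 1/period_s."""
    counts = np.asarray(counts, dtype=float)
    m = int(round(period_s / bin_s))
    n_cycles = counts.size // m
    folded = counts[:n_cycles * m].reshape(n_cycles, m).mean(axis=0) / bin_s
    spec = np.fft.rfft(folded)
    freqs = np.fft.rfftfreq(m, d=bin_s)
    amps = 2.0 * np.abs(spec) / m
    amps[0] /= 2.0
    return freqs, amps


def contrast_response(counts, bin_s: float, contrast_trace,
                      n_bins: int = 20):
    """Contrast-response curve and its half-maximum contrast C_1/2.

    Rates are averaged within equal-width instantaneous-contrast bins over
    [0, 1].  C_1/2 is the lowest contrast at which the linearly
    interpolated curve crosses (max + baseline)/2, with the baseline taken
    from the lowest-contrast bin.  Returns ``(curve, c_half)`` where
    ``curve`` has columns ``contrast`` (bin center) and ``rate``; ``c_half``
    is NaN when the curve never crosses its half-maximum.
    """
    counts = np.asarray(counts, dtype=float)
    trace = np.tile(np.asarray(contrast_trace, dtype=float),
                    int(np.ceil(counts.size / len(contrast_trace))))
    trace = trace[:counts.size]
    if trace.size != counts.size:
        raise ValueError("contrast trace and counts are misaligned")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(trace, edges) - 1, 0, n_bins - 1)
    rate_sum = np.bincount(idx, weights=counts, minlength=n_bins)
    n_per = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        rates = np.where(n_per > 0, rate_sum / (n_per * bin_s), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    valid = ~np.isnan(rates)
    curve = pd.DataFrame({"contrast": centers[valid], "rate": rates[valid]})

    c = curve["contrast"].to_numpy()
    r = curve["rate"].to_numpy()
    if len(r) < 2:
        return curve, float("nan")
    baseline = r[0]
    if r.max() <= baseline + 1e-12:  # contrast-independent rate
        return curve, float("nan")
    half = (r.max() + baseline) / 2.0
    c_half = float("nan")
    above = r >= half
    for i in range(1, len(r)):
        if above[i] and not above[i - 1]:
            frac = (half - r[i - 1]) / (r[i] - r[i - 1])
            c_half = float(c[i - 1] + frac * (c[i] - c[i - 1]))
            break
    return curve, c_half


# ---------------------------------------------------------------------------
# Waveform classification

def classify_waveform(trough_to_peak_ms: float, slope_at_half_ms: float,
                      t2p_threshold_ms: float = 0.5,
                      slope_threshold: float = 0.0) -> str:
    """Classify a unit as broad- or narrow-spiking from its waveform.

    Narrow-spiking (putative fast-spiking inhibitory): trough-to-peak time
    below ``t2p_threshold_ms`` *and* repolarization slope 0.5 ms after the
    trough at or below ``slope_threshold``.  Everything else is broad.
    """
    if not (np.isfinite(trough_to_peak_ms) and np.isfinite(slope_at_half_ms)):
        raise ValueError("waveform features must be finite")
    narrow = (trough_to_peak_ms < t2p_threshold_ms
              and slope_at_half_ms <= slope_threshold)
    return "narrow" if narrow else "broad"


# ---------------------------------------------------------------------------
# Vectorized population fast paths (no tuning fits)

def peak_grating_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Peak baseline-subtracted grating response per unit and eye, for a
    whole-population trial table at once.

    Returns one row per unit: ``unit_id, spont_rate,
    peak_grating_resp_contra, peak_grating_resp_ipsi``.
    """
    rate = trials["spike_count"] / trials["duration_s"]
    blanks = trials["is_blank"]
    spont = rate[blanks].groupby(trials.loc[blanks, "unit_id"]).mean()
    evoked = (rate[~blanks]
              .groupby([trials.loc[~blanks, "unit_id"],
                        trials.loc[~blanks, "eye"],
                        trials.loc[~blanks, "direction_deg"],
                        trials.loc[~blanks, "sf_cpd"]])
              .mean()
              .groupby(level=["unit_id", "eye"]).max()
              .unstack("eye"))
    out = pd.DataFrame({"spont_rate": spont})
    for eye in ("contra", "ipsi"):
        out[f"peak_grating_resp_{eye}"] = evoked[eye] - spont
    return out.reset_index().rename(columns={"index": "unit_id"})


def f1_table(noise_responses: pd.DataFrame, bin_s: float,
             period_s: float = 10.0) -> pd.DataFrame:
    """F1 response per unit and eye from a population noise-response
    table (columns ``unit_id, eye, bin_start_s, count``)."""
    rows = []
    for (uid, eye), grp in noise_responses.groupby(["unit_id", "eye"]):
        counts = grp.sort_values("bin_start_s")["count"].to_numpy()
        rows.append({"unit_id": uid, "eye": eye,
                     "f1": f1_response(counts, bin_s, period_s)})
    return (pd.DataFrame(rows)
            .pivot(index="unit_id", columns="eye", values="f1")
            .rename(columns={"contra": "f1_contra", "ipsi": "f1_ipsi"})
            .reset_index())


# ---------------------------------------------------------------------------
# Orchestration: one metrics row per unit

def _unit_grating_metrics(trials, unit_id, eye, spont):
    """Per-eye grating metrics: peak evoked response, theta_pref, fit,
    OSI, HWHM, SF preference."""
    resp = condition_responses(trials, unit_id, eye, spont=spont)
    peak = float(resp["response"].max())

    by_dir = resp.groupby("direction_deg")["response"].mean()
    out = {"peak": peak, "theta_pref": np.nan, "osi": np.nan,
           "hwhm": np.nan, "sf_pref": np.nan, "fit": None}
    try:
        theta_pref = preferred_orientation(by_dir.index.to_numpy(),
                                           by_dir.to_numpy())
    except UndefinedMetricError:
        return out
    fit = fit_orientation_tuning(by_dir.index.to_numpy(), by_dir.to_numpy(),
                                 theta_pref)
    out["theta_pref"] = np.mod(fit.theta_pref_deg, 180.0)
    out["fit"] = fit
    if fit.converged:
        out["osi"] = fit.osi
        out["hwhm"] = fit.hwhm_deg

    # SF curve at the stimulus directions closest to the preferred
    # orientation (both drift directions of that orientation)
    dirs = resp["direction_deg"].to_numpy()
    ori_dist = np.abs(np.mod(dirs - theta_pref + 90.0, 180.0) - 90.0)
    at_pref = resp[np.isclose(ori_dist, ori_dist.min())]
    if len(at_pref) >= 4:
        sf_curve = at_pref.groupby("sf_cpd")["response"].mean()
        try:
            sffit = fit_sf_tuning(sf_curve.index.to_numpy(),
                                  sf_curve.to_numpy())
            out["sf_pref"] = sffit.sf_pref_cpd
        except ValueError:
            pass
    return out


def compute_unit_metrics(trials: pd.DataFrame,
                         noise_responses: pd.DataFrame | None = None,
                         waveform_features: pd.DataFrame | None = None,
                         noise_bin_s: float | None = None,
                         contrast_period_s: float = 10.0) -> pd.DataFrame:
    """Compute the full metrics row for every unit in a trial table.

    ``noise_responses`` (optional) must have columns ``unit_id, eye,
    bin_start_s, count``; ``waveform_features`` (optional) columns
    ``unit_id, trough_to_peak_ms, slope_at_half_ms``.  Returns one row per
    unit with spontaneous rate, per-eye peak grating responses and tuning
    metrics, grating/noise ODI, F1 responses, C_1/2 and cell class.
    """
    rows = []
    unit_ids = sorted(trials["unit_id"].unique())
    wf = (waveform_features.set_index("unit_id")
          if waveform_features is not None else None)

    noise_by_unit = {}
    if noise_responses is not None:
        if noise_bin_s is None:
            starts = np.sort(noise_responses["bin_start_s"].unique())
            noise_bin_s = float(np.min(np.diff(starts)))
        noise_by_unit = dict(tuple(noise_responses.groupby("unit_id")))

    for uid in unit_ids:
        row: dict = {"unit_id": uid}
        spont = spontaneous_rate(trials, uid)
        row["spont_rate"] = spont

        per_eye = {eye: _unit_grating_metrics(trials, uid, eye, spont)
                   for eye in ("contra", "ipsi")}
        row["peak_grating_resp_contra"] = per_eye["contra"]["peak"]
        row["peak_grating_resp_ipsi"] = per_eye["ipsi"]["peak"]
        row["osi_contra"] = per_eye["contra"]["osi"]
        row["osi_ipsi"] = per_eye["ipsi"]["osi"]
        row["theta_pref_contra"] = per_eye["contra"]["theta_pref"]
        row["theta_pref_ipsi"] = per_eye["ipsi"]["theta_pref"]
        row["hwhm_contra"] = per_eye["contra"]["hwhm"]
        row["hwhm_ipsi"] = per_eye["ipsi"]["hwhm"]
        row["sf_pref_contra"] = per_eye["contra"]["sf_pref"]
        row["sf_pref_ipsi"] = per_eye["ipsi"]["sf_pref"]

        row["responsive_grating"] = (
            per_eye["contra"]["peak"] >= RESPONSIVE_GRATING_SP_S
            or per_eye["ipsi"]["peak"] >= RESPONSIVE_GRATING_SP_S)
        try:
            row["odi_grating"] = odi_unit(per_eye["contra"]["peak"],
                                          per_eye["ipsi"]["peak"])
        except UndefinedMetricError:
            row["odi_grating"] = np.nan

        if (np.isfinite(row["theta_pref_contra"])
                and np.isfinite(row["theta_pref_ipsi"])):
            row["dO_abs_deg"] = abs(orientation_difference(
                row["theta_pref_contra"], row["theta_pref_ipsi"]))
        else:
            row["dO_abs_deg"] = np.nan

        # noise-movie metrics
        row["f1_contra"] = row["f1_ipsi"] = np.nan
        row["c_half_contra"] = row["c_half_ipsi"] = np.nan
        if uid in noise_by_unit:
            grp = noise_by_unit[uid]
            for eye in ("contra", "ipsi"):
                sub = grp[grp["eye"] == eye].sort_values("bin_start_s")
                if len(sub) == 0:
                    continue
                counts = sub["count"].to_numpy()
                try:
                    row[f"f1_{eye}"] = f1_response(
                        counts, noise_bin_s, contrast_period_s)
                except ValueError:
                    continue
        row["responsive_noise"] = bool(
            (np.nan_to_num(row["f1_contra"]) > RESPONSIVE_NOISE_F1)
            or (np.nan_to_num(row["f1_ipsi"]) > RESPONSIVE_NOISE_F1))
        if np.isfinite(row["f1_contra"]) and np.isfinite(row["f1_ipsi"]):
            try:
                row["odi_noise"] = odi_unit(row["f1_contra"],
                                            row["f1_ipsi"])
            except UndefinedMetricError:
                row["odi_noise"] = np.nan
        else:
            row["odi_noise"] = np.nan

        if wf is not None and uid in wf.index:
            row["cell_class"] = classify_waveform(
                wf.at[uid, "trough_to_peak_ms"],
                wf.at[uid, "slope_at_half_ms"])
        else:
            row["cell_class"] = "unclassified"
        rows.append(row)
    return pd.DataFrame(rows)
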