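"""Fluorescence-polarization binding analysis.

Saturation (direct-binding) curves are fit to the 1:1 ligand-depletion
quadratic model; displacement (competition) curves to a logistic in log
concentration yielding an IC50, which is converted to the competitor's
dissociation constant K_i with the exact competitive-equilibrium algebra
(free-species concentrations at 0% and 50% inhibition).  All
concentrations are handled internally in uM; FP signals in mP.

The closed-form K_i conversion is validated in the test suite against the
numeric three-species equilibrium solver implemented here
(:func:`competitive_complex`), which shares no algebra with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

NO_BINDING_SPAN_FRACTION = 0.2  # minimum relative signal span to call binding

ENABLING = "enabling"
DISABLING = "disabling"
NEUTRAL = "neutral"


# --------------------------------------------------------------------------
# Equilibrium models
# --------------------------------------------------------------------------

def complex_concentration(p_total, l_total, kd):
    """[PL] under 1:1 binding with ligand depletion (quadratic model)."""
    p_total = np.asarray(p_total, dtype=float)
    s = p_total + l_total + kd
    return (s - np.sqrt(s * s - 4.0 * p_total * l_total)) / 2.0


def saturation_signal(p_total, l_total, kd, s_free, s_bound):
    """FP signal of a probe at total protein series ``p_total``."""
    pl = complex_concentration(p_total, l_total, kd)
    return s_free + (s_bound - s_free) * pl / l_total


def competitive_complex(p_total, l_total, i_total, kd_probe, ki):
    """Probe-protein complex [PL] in the three-species competition system.

    Solves the coupled mass balances for protein P, labeled probe L and
    unlabeled competitor I with the two equilibria P+L<->PL (kd_probe) and
    P+I<->PI (ki) by root-finding on the free protein concentration.
    """
    if min(p_total, l_total, kd_probe, ki) <= 0 or i_total < 0:
        raise ValueError("concentrations and constants must be positive")

    def balance(p_free):
        pl = p_free * l_total / (kd_probe + p_free)
        pi = p_free * i_total / (ki + p_free)
        return p_free + pl + pi - p_total

    p_free = brentq(balance, 0.0, p_total, xtol=1e-15, rtol=1e-14)
    return p_free * l_total / (kd_probe + p_free)


def displacement_signal(i_total, p_total, l_total, kd_probe, ki, s_free, s_bound):
    i_total = np.atleast_1d(np.asarray(i_total, dtype=float))
    pl = np.array(
        [competitive_complex(p_total, l_total, i, kd_probe, ki) for i in i_total]
    )
    return s_free + (s_bound - s_free) * pl / l_total


# --------------------------------------------------------------------------
# Curve fitting
# --------------------------------------------------------------------------

@dataclass
class SaturationFit:
    kd: float
    signal_free: float
    signal_bound: float
    kd_stderr: float
    covariance: np.ndarray
    at_bound: bool = False


@dataclass
class DisplacementFit:
    ic50: float | None
    slope: float | None
    top: float | None
    bottom: float | None
    ic50_stderr: float | None
    no_binding: bool


class FitError(RuntimeError):
    pass


def fit_saturation(protein_total, signal, probe_total) -> SaturationFit:
    """Fit a direct-binding FP curve to the quadratic depletion model.

    Initial guesses: S_free/S_bound from the signal extremes and K_d from
    the protein concentration nearest the half-maximal signal.
    """
    x = np.asarray(protein_total, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points to fit a saturation curve")
    s_free0, s_bound0 = float(y.min()), float(y.max())
    half = (s_free0 + s_bound0) / 2.0
    kd0 = float(x[np.argmin(np.abs(y - half))]) or float(np.median(x[x > 0]))

    def model(p, kd, s_free, s_bound):
        return saturation_signal(p, probe_total, kd, s_free, s_bound)

    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[kd0, s_free0, s_bound0],
            bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"saturation fit did not converge: {exc}") from exc
    kd_err = float(np.sqrt(pcov[0, 0]))
    return SaturationFit(
        kd=float(popt[0]), signal_free=float(popt[1]), signal_bound=float(popt[2]),
        kd_stderr=kd_err, covariance=pcov, at_bound=bool(popt[0] <= 2e-9),
    )


def fit_displacement(
    competitor_total, signal, fixed_slope: bool = False
) -> DisplacementFit:
    """Fit a descending logistic to a displacement curve, yielding IC50.

    The model is ``y = bottom + (top - bottom) / (1 + (x / ic50)^h)`` with
    h free by default or fixed at 1 (``fixed_slope=True``).  If the
    observed signal span is below 20% of the maximum signal the curve is
    flagged "no binding" and no IC50 is reported.
    """
    x = np.asarray(competitor_total, dtype=float)
    y = np.asarray(signal, dtype=float)
    mask = x > 0
    if mask.sum() < 4:
        raise ValueError("need at least 4 non-zero competitor concentrations")
    span = float(y.max() - y.min())
    if span < NO_BINDING_SPAN_FRACTION * abs(float(y.max())):
        return DisplacementFit(None, None, None, None, None, no_binding=True)

    x_fit, y_fit = x[mask], y[mask]
    half = (y_fit.max() + y_fit.min()) / 2.0
    ic50_0 = float(x_fit[np.argmin(np.abs(y_fit - half))])

    if fixed_slope:
        def model(xx, ic50, top, bottom):
            return bottom + (top - bottom) / (1.0 + xx / ic50)
        p0 = [ic50_0, float(y_fit.max()), float(y_fit.min())]
        lower = [1e-12, -np.inf, -np.inf]
        upper = [np.inf, np.inf, np.inf]
    else:
        def model(xx, ic50, top, bottom, h):
            return bottom + (top - bottom) / (1.0 + (xx / ic50) ** h)
        p0 = [ic50_0, float(y_fit.max()), float(y_fit.min()), 1.0]
        lower = [1e-12, -np.inf, -np.inf, 0.1]
        upper = [np.inf, np.inf, np.inf, 10.0]

    try:
        popt, pcov = curve_fit(model, x_fit, y_fit, p0=p0,
                               bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"displacement fit did not converge: {exc}") from exc
    return DisplacementFit(
        ic50=float(popt[0]),
        slope=1.0 if fixed_slope else float(popt[3]),
        top=float(popt[1]), bottom=float(popt[2]),
        ic50_stderr=float(np.sqrt(pcov[0, 0])),
        no_binding=False,
    )


# --------------------------------------------------------------------------
# IC50 -> Ki conversion (exact competitive-equilibrium analysis)
# --------------------------------------------------------------------------

def ki_from_ic50(ic50, probe_kd, probe_total, protein_total) -> float:
    """Competitor K_i from a displacement IC50 (exact analysis).

    Works from the free-species concentrations: at 0% inhibition the
    probe-protein complex is the quadratic-model [PL]0; at 50% inhibition
    [PL]50 = [PL]0 / 2, from which the free probe, free protein,
    competitor-bound protein and free competitor follow by mass balance,
    and K_i = [P]50 [I]50 / [PI]50.  No approximation beyond 1:1
    equilibria is involved, so the result matches a numeric three-species
    solver to machine precision.
    """
    if min(probe_kd, probe_total, protein_total) <= 0 or ic50 < 0:
        raise ValueError("all inputs must be positive (ic50 >= 0)")
    pl0 = complex_concentration(protein_total, probe_total, probe_kd)
    pl50 = pl0 / 2.0
    l50 = probe_total - pl50
    p50 = probe_kd * pl50 / l50
    pi50 = protein_total - p50 - pl50
    if pi50 <= 0:
        raise ValueError(
            "inconsistent inputs: no competitor-bound protein at 50% inhibition"
        )
    i50 = ic50 - pi50
    if i50 <= 0:
        raise ValueError(
            f"ic50 ({ic50}) below the theoretical minimum ({pi50}) for this "
            "complex concentration"
        )
    return float(p50 * i50 / pi50)


def back_calculate_active_concentration(
    protein_nominal, signal, probe_total, probe_kd
) -> tuple[float, float]:
    """Active protein fraction from a saturation curve with known probe K_d.

    Refits the quadratic model with nominal protein concentrations scaled
    by a multiplicative active fraction (K_d held fixed).  Returns
    ``(fraction, stderr)``; the fraction is constrained to (0, 1.5].
    """
    x = np.asarray(protein_nominal, dtype=float)
    y = np.asarray(signal, dtype=float)

    def model(p_nom, fraction, s_free, s_bound):
        return saturation_signal(p_nom * fraction, probe_total, probe_kd,
                                 s_free, s_bound)

    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[1.0, float(y.min()), float(y.max())],
            bounds=([1e-6, -np.inf, -np.inf], [1.5, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"active-fraction fit did not converge: {exc}") from exc
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


# --------------------------------------------------------------------------
# Fold changes with bound/no-binding propagation
# --------------------------------------------------------------------------

def parse_kd(cell) -> tuple[float | None, str]:
    """Parse a K_D cell: numeric uM value, "<x" upper bound, or "n.b.".

    Returns ``(value_or_None, kind)`` with kind in
    {"numeric", "upper_bound", "no_binding"}.
    """
    if isinstance(cell, (int, float)):
        if cell <= 0:
            raise ValueError(f"non-positive K_D: {cell!r}")
        return float(cell), "numeric"
    text = str(cell).strip()
    if text in ("n.b.", "n.b", "nb"):
        return None, "no_binding"
    if text.startswith("<"):
        v = float(text[1:].replace(",", ""))
        if v <= 0:
            raise ValueError(f"non-positive K_D bound: {cell!r}")
        return v, "upper_bound"
    try:
        v = float(text.replace(",", ""))
    except ValueError as exc:
        raise ValueError(f"unparseable K_D cell: {cell!r}") from exc
    if v <= 0:
        raise ValueError(f"non-positive K_D: {cell!r}")
    return v, "numeric"


def fold_change(kd_reference, kd_variant, threshold: float = 2.0):
    """Affinity fold change and its direction between two K_D values.

    For numeric pairs, fold = max(r, 1/r) with r = kd_reference/kd_variant;
    the direction is enabling when the variant binds at least
    ``threshold``-fold tighter, disabling when at least ``threshold``-fold
    weaker, else neutral.  Bounds propagate directionally: a variant
    "n.b." is a disabling change of unbounded fold; a variant "<x" gives a
    fold of at least kd_reference/x (enabling only if that already clears
    the threshold).
    """
    ref, ref_kind = parse_kd(kd_reference)
    var, var_kind = parse_kd(kd_variant)

    if var_kind == "no_binding":
        if ref_kind == "no_binding":
            return 1.0, NEUTRAL
        return float("inf"), DISABLING
    if ref_kind == "no_binding":
        return float("inf"), ENABLING

    if var_kind == "upper_bound" and ref_kind == "numeric":
        fold = ref / var  # at least this fold
        return fold, (ENABLING if fold >= threshold else NEUTRAL)
    if ref_kind == "upper_bound" and var_kind == "numeric":
        fold = var / ref
        return fold, (DISABLING if fold >= threshold else NEUTRAL)
    if ref_kind == "upper_bound" and var_kind == "upper_bound":
        return 1.0, NEUTRAL  # two bounds establish no direction

    r = ref / var
    fold = max(r, 1.0 / r)
    if fold < threshold:
        return fold, NEUTRAL
    return fold, (ENABLING if var < ref else DISABLING)
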