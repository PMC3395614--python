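"""3-parameter logistic dose-response fitting, agonist gating, pair comparison.

The response of a receptor to an odorant over a concentration series is
modeled as a 3-parameter logistic (Hill slope fixed at 1):

    y(x) = bottom + (top - bottom) / (1 + 10**(logEC50 - x)),   x = log10 [M]

Potency is EC50 (lower = more potent); efficacy is the span (top - bottom,
the dynamic range). An odorant counts as an agonist only if (1) the 95%
confidence intervals of top and bottom do not overlap, (2) the standard
error of logEC50 is below 1 log unit, and (3) the extra-sum-of-squares F
test shows the receptor responds more than the vector-only control.

Two receptors tested against the same ligand are compared by the
extra-sum-of-squares test (one shared curve vs two separate curves,
F with 3 numerator df) and classified as indistinguishable, hyper-/
hypofunctional (concordant potency and efficacy shift) or undefined
(discordant shifts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseDataset",
    "LogisticFit",
    "ExtraSSResult",
    "GateDecision",
    "PairClassification",
    "logistic3",
    "fit_3pl",
    "agonist_gate",
    "extra_ss_compare",
    "classify_pair",
    "normalize_curve_set",
]


class DoseResponseError(ValueError):
    pass


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicated responses of one receptor to one odor over a dilution series.

    Concentrations are molar and strictly positive (the reference design is
    log-spaced 10 nM to 10 mM); ``responses`` has shape (n_conc, n_rep).
    """

    receptor: str
    odor: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if (conc <= 0).any():
            raise DoseResponseError("concentrations must be strictly positive (molar)")
        if len(np.unique(conc)) < 4:
            raise DoseResponseError("need >= 4 distinct concentrations")
        if resp.shape[0] != conc.size:
            raise DoseResponseError(
                f"responses rows ({resp.shape[0]}) != concentrations ({conc.size})"
            )
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    @property
    def log_conc(self) -> np.ndarray:
        return np.log10(self.concentrations)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (log10 concentration, response) observation pairs."""
        n_rep = self.responses.shape[1]
        x = np.repeat(self.log_conc, n_rep)
        return x, self.responses.ravel()

    @property
    def n_obs(self) -> int:
        return self.responses.size


def logistic3(x: np.ndarray, bottom: float, top: float, logec50: float) -> np.ndarray:
    # exponent clipped to keep extreme optimizer excursions finite
    expo = np.clip(logec50 - np.asarray(x, dtype=float), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares 3PL fit with asymptotic uncertainties.

    Standard errors come from the curvature (J'J) at the optimum scaled by
    the residual variance; 95% CIs use the t quantile with df = n - 3.
    ``degenerate`` marks fits whose top and bottom CIs overlap (flat or
    noise-dominated data); ``converged`` False marks optimizer failure —
    neither raises, so batch processing can carry flagged rows.
    """

    bottom: float
    top: float
    logec50: float
    se_bottom: float
    se_top: float
    se_logec50: float
    ci_bottom: tuple[float, float]
    ci_top: tuple[float, float]
    ci_logec50: tuple[float, float]
    ss: float
    df: int
    n: int
    converged: bool
    degenerate: bool

    @property
    def span(self) -> float:
        return self.top - self.bottom

    @property
    def ec50(self) -> float:
        return 10.0 ** self.logec50


def _fit_xy(x: np.ndarray, y: np.ndarray, n_params: int = 3) -> LogisticFit:
    """Multi-start least-squares core shared by single and pooled fits."""
    lo, hi = x.min(), x.max()
    b0, t0 = float(y.min()), float(y.max())
    if t0 == b0:
        t0 = b0 + 1e-12
    starts = np.linspace(lo - 1.0, hi + 1.0, 7)

    best = None
    for e0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: logistic3(x, *p) - y,
                x0=[b0, t0, e0],
                method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        nan = float("nan")
        return LogisticFit(nan, nan, nan, nan, nan, nan, (nan, nan), (nan, nan),
                           (nan, nan), nan, x.size - n_params, x.size, False, True)

    bottom, top, logec50 = best.x
    resid = best.fun
    ss = float(resid @ resid)
    df = x.size - n_params
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (ss / df if df > 0 else np.nan)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.inf)
    tq = stats.t.ppf(0.975, df) if df > 0 else np.inf
    cis = [(v - tq * s, v + tq * s) for v, s in zip(best.x, se)]
    degenerate = cis[0][1] >= cis[1][0]  # bottom CI upper >= top CI lower
    return LogisticFit(
        float(bottom), float(top), float(logec50),
        float(se[0]), float(se[1]), float(se[2]),
        cis[0], cis[1], cis[2], ss, df, x.size,
        bool(best.success), bool(degenerate),
    )


def fit_3pl(data: DoseResponseDataset) -> LogisticFit:
    """Fit the 3-parameter logistic by multi-start least squares.

    Initial logEC50 values span the tested concentration range (plus one
    decade either side); bottom/top start at the response extremes. The best
    of the starts by residual sum of squares wins.
    """
    x, y = data.xy()
    return _fit_xy(x, y)


@dataclass(frozen=True)
class ExtraSSResult:
    """Extra-sum-of-squares F test: one shared 3PL vs two separate 3PLs.

    F = ((SS_pooled - SS_separate) / 3) / (SS_separate / df_separate) with
    df_separate = n_total - 6; small p means the two datasets genuinely need
    different curves.
    """

    F: float
    df_num: int
    df_den: int
    p: float
    ss_pooled: float
    ss_separate: float
    exact_fit: bool = False


def extra_ss_compare(data_a: DoseResponseDataset, data_b: DoseResponseDataset) -> ExtraSSResult:
    xa, ya = data_a.xy()
    xb, yb = data_b.xy()
    fit_a = _fit_xy(xa, ya)
    fit_b = _fit_xy(xb, yb)
    pooled = _fit_xy(np.concatenate([xa, xb]), np.concatenate([ya, yb]))
    ss_sep = fit_a.ss + fit_b.ss
    ss_pool = pooled.ss
    n_total = xa.size + xb.size
    df_den = n_total - 6
    df_num = 3
    # numerically-zero separate SS (perfect fits) relative to the data scale
    scale = float(ya @ ya + yb @ yb) + 1e-300
    if ss_sep <= 1e-12 * scale:
        if ss_pool > 1e-12 * scale:
            return ExtraSSResult(float("inf"), df_num, df_den, 0.0, ss_pool, ss_sep, True)
        return ExtraSSResult(0.0, df_num, df_den, 1.0, ss_pool, ss_sep, True)
    F = max(0.0, (ss_pool - ss_sep) / df_num / (ss_sep / df_den))
    p = float(stats.f.sf(F, df_num, df_den))
    return ExtraSSResult(float(F), df_num, df_den, p, float(ss_pool), float(ss_sep))


@dataclass(frozen=True)
class GateDecision:
    agonist: bool
    reasons: tuple[str, ...]  # names of failed criteria; empty when agonist
    control_test: ExtraSSResult | None = None


def agonist_gate(
    fit: LogisticFit,
    or_data: DoseResponseDataset,
    control_data: DoseResponseDataset,
    alpha: float = 0.05,
) -> GateDecision:
    """Apply the three agonist criteria; report every failed one by name.

    Criteria: "ci_overlap" (top/bottom 95% CIs overlap), "ec50_sd"
    (SE of logEC50 >= 1 log unit), "vs_control" (extra-SS test against the
    vector-only control not significant at alpha).
    """
    if control_data is None:
        raise DoseResponseError("vector-control dataset required for the agonist gate")
    reasons = []
    if not fit.converged:
        reasons.append("not_converged")
    if fit.degenerate:
        reasons.append("ci_overlap")
    if not (fit.se_logec50 < 1.0):
        reasons.append("ec50_sd")
    ctrl = extra_ss_compare(or_data, control_data)
    if not (ctrl.p < alpha):
        reasons.append("vs_control")
    return GateDecision(agonist=not reasons, reasons=tuple(reasons), control_test=ctrl)


@dataclass(frozen=True)
class PairClassification:
    """Functional-change label for a receptor pair on a shared ligand.

    "indistinguishable" when the shared curve suffices (p >= alpha);
    "a_hyperfunctional" when A is both more potent (lower EC50) and more
    efficacious (larger span), "a_hypofunctional" for the mirror case,
    "undefined" for discordant shifts, "not_comparable" when either member
    fails the agonist gate.
    """

    label: str
    extra_ss: ExtraSSResult | None
    delta_logec50: float
    delta_span: float
    fit_a: LogisticFit | None = None
    fit_b: LogisticFit | None = None
    gate_a: GateDecision | None = None
    gate_b: GateDecision | None = None


def classify_pair(
    data_a: DoseResponseDataset,
    data_b: DoseResponseDataset,
    control_a: DoseResponseDataset | None = None,
    control_b: DoseResponseDataset | None = None,
    alpha: float = 0.05,
) -> PairClassification:
    """Classify the functional relationship of two receptors to one ligand.

    When vector controls are supplied, both members must pass the agonist
    gate first (else "not_comparable"). The direction test uses the fitted
    EC50 and span: concordant advantage -> hyper/hypo, discordant ->
    undefined.
    """
    fit_a = fit_3pl(data_a)
    fit_b = fit_3pl(data_b)
    gate_a = gate_b = None
    if control_a is not None or control_b is not None:
        gate_a = agonist_gate(fit_a, data_a, control_a or control_b, alpha)
        gate_b = agonist_gate(fit_b, data_b, control_b or control_a, alpha)
        if not (gate_a.agonist and gate_b.agonist):
            return PairClassification(
                "not_comparable", None,
                fit_a.logec50 - fit_b.logec50, fit_a.span - fit_b.span,
                fit_a, fit_b, gate_a, gate_b,
            )
    ess = extra_ss_compare(data_a, data_b)
    d_ec = fit_a.logec50 - fit_b.logec50
    d_span = fit_a.span - fit_b.span
    if ess.p >= alpha:
        label = "indistinguishable"
    else:
        a_more_potent = d_ec < 0
        a_more_efficacious = d_span > 0
        if a_more_potent and a_more_efficacious:
            label = "a_hyperfunctional"
        elif (not a_more_potent) and (not a_more_efficacious):
            label = "a_hypofunctional"
        else:
            label = "undefined"
    return PairClassification(label, ess, d_ec, d_span, fit_a, fit_b, gate_a, gate_b)


def normalize_curve_set(
    datasets: dict[str, DoseResponseDataset],
    fits: dict[str, LogisticFit] | None = None,
    mode: str = "max_of_set",
    reference: str | None = None,
) -> dict[str, np.ndarray]:
    """Display scaling of a set of curves (never feeds the statistics).

    mode="max_of_set": subtract the fitted bottom of the member with the
    largest fitted top, divide by that member's span — its peak maps to 1.
    mode="reference": divide each response by the reference member's fitted
    top, no baseline subtraction (shows baseline differences).
    """
    if not datasets:
        raise DoseResponseError("need at least one dataset")
    fits = fits or {name: fit_3pl(d) for name, d in datasets.items()}
    if mode == "max_of_set":
        top_member = max(fits, key=lambda r: fits[r].top)
        baseline = fits[top_member].bottom
        denom = fits[top_member].span
    elif mode == "reference":
        if reference is None or reference not in fits:
            raise DoseResponseError("reference mode requires a reference member")
        baseline = 0.0
        denom = fits[reference].top
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise DoseResponseError("zero span/top in the normalizing member")
    return {name: (d.responses - baseline) / denom for name, d in datasets.items()}
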