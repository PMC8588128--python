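"""Predictive-uncertainty measures, rejection threshold, and evaluation.

Given a predictive distribution {p_t; 1 <= t <= T} over C classes with
mean p*, five measures are computed (entropies in bits):

* variation ratio        VR   = 1 - f_{c*}/T, with c* the mode of the
                                per-pass argmax classes (range [0, 1-1/C])
* predictive entropy     H    = -sum_j p*_j log2 p*_j, and Hn = H/log2 C
* mutual information     I    = H(p*) - (1/T) sum_t H(p_t)   (epistemic)
* total variance         Vtot = (1/T) sum_j sum_t (p_jt - p*_j)^2
* margin of confidence   M    = mean_t d_t, d_t = p_ct - max_{j!=c} p_jt
                                with c = argmax p* fixed across passes;
                                d_t (and M) can be negative.

M is a sample mean of T values, so under a normality assumption a
prediction is "certain" exactly when zero lies outside the confidence
interval of M, i.e. M > M_hat = sigma_d * z_{1-alpha/2} / sqrt(T), where
sigma_d is the sample standard deviation of {d_t}.  The threshold depends
only on the predictive distribution, never on the data: a fully
consistent model (sigma_d ~ 0) is never rejected, however small M is.

Certainty evaluation counts the four prediction subsets
(correct/incorrect x certain/uncertain) and reports

    Rc  = (Ncc+Nic)/N          certain ratio
    Rcc = Ncc/(Ncc+Nic)        accuracy among certain predictions
    Riu = Niu/(Niu+Nic)        recall of errors by the reject rule
    UA  = (Ncc+Niu)/N          uncertainty accuracy

The Bhattacharyya distance between the histograms of a measure over
correct vs incorrect predictions quantifies how well that measure
separates the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcd import PredictiveDistribution

__all__ = [
    "UncertaintyMeasures",
    "CertaintyDecision",
    "UncertaintyReport",
    "variation_ratio",
    "predictive_entropy",
    "mutual_information",
    "total_variance",
    "margin_of_confidence",
    "bhattacharyya_distance",
    "measure_separation",
    "margin_threshold",
    "decide",
    "compute_measures",
    "evaluate_uncertainty",
    "sweep_threshold_multiplier",
]

_EPS_HIST = 1e-12


@dataclass
class UncertaintyMeasures:
    VR: float
    H: float
    Hn: float
    I: float
    Vtot: float
    M: float
    sigma_d: float
    d: np.ndarray


@dataclass
class CertaintyDecision:
    predicted_class: int
    M: float
    sigma_d: float
    threshold: float
    alpha: float
    certain: bool


@dataclass
class UncertaintyReport:
    N_cc: int
    N_ic: int
    N_cu: int
    N_iu: int

    @property
    def N(self) -> int:
        return self.N_cc + self.N_ic + self.N_cu + self.N_iu

    @property
    def Rc(self) -> float:
        return (self.N_cc + self.N_ic) / self.N

    @property
    def Rcc(self) -> float:
        den = self.N_cc + self.N_ic
        return self.N_cc / den if den else float("nan")

    @property
    def Riu(self) -> float:
        den = self.N_iu + self.N_ic
        return self.N_iu / den if den else float("nan")

    @property
    def UA(self) -> float:
        return (self.N_cc + self.N_iu) / self.N


def _entropy_bits(p: np.ndarray, axis=-1) -> np.ndarray:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    p = np.asarray(p, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -term.sum(axis=axis)


def variation_ratio(pd_: PredictiveDistribution) -> float:
    """Dispersion of the per-pass predicted classes around their mode.

    Per-pass argmax ties and mode ties both break toward the lowest class
    index.  Maximum 1 - 1/C (modes maximally dispersed), minimum 0.
    """
    ct = np.argmax(pd_.P, axis=1)
    counts = np.bincount(ct, minlength=pd_.n_classes)
    return 1.0 - counts.max() / pd_.T


def predictive_entropy(pd_: PredictiveDistribution) -> tuple[float, float]:
    """(H, Hn): entropy of p* in bits and its log2(C)-normalized form."""
    H = float(_entropy_bits(pd_.p_star))
    return H, H / np.log2(pd_.n_classes)


def mutual_information(pd_: PredictiveDistribution) -> float:
    """Epistemic uncertainty: H(p*) minus the mean per-pass entropy."""
    I = float(_entropy_bits(pd_.p_star) - _entropy_bits(pd_.P, axis=1).mean())
    return 0.0 if abs(I) < 1e-9 else I


def total_variance(pd_: PredictiveDistribution) -> float:
    """Sum over classes of the per-class population variance across passes."""
    return float(np.sum((pd_.P - pd_.p_star) ** 2) / pd_.T)


def margin_of_confidence(pd_: PredictiveDistribution) -> tuple[float, float, np.ndarray]:
    """(M, sigma_d, d): per-pass margins against the MCD predicted class.

    c = argmax p* is fixed; d_t = p_ct - max_{j != c} p_jt may be
    negative on passes that prefer another class.  sigma_d is the sample
    (ddof=1) standard deviation, defined as 0 for T=1.
    """
    if pd_.n_classes < 2:
        raise ValueError("margin of confidence needs C >= 2")
    c = pd_.predicted_class
    others = np.delete(pd_.P, c, axis=1)
    d = pd_.P[:, c] - others.max(axis=1)
    M = float(d.mean())
    sigma_d = float(d.std(ddof=1)) if pd_.T > 1 else 0.0
    return M, sigma_d, d


def bhattacharyya_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """DB = -ln(sum_x sqrt(p(x) q(x))) between two normalized histograms."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError("histograms must share their binning")
    return float(-np.log(np.sum(np.sqrt(h1 * h2)) + _EPS_HIST))


def measure_separation(
    correct_values: np.ndarray, incorrect_values: np.ndarray, n_bins: int = 20
) -> float:
    """Bhattacharyya distance between the histograms of an uncertainty
    measure over correct vs incorrect predictions (equal-width bins over
    the pooled range)."""
    cv = np.asarray(correct_values, dtype=np.float64)
    iv = np.asarray(incorrect_values, dtype=np.float64)
    if len(cv) == 0 or len(iv) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([cv, iv])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        hi = lo + 1.0  # all values identical: everything in one bin
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(cv, bins=edges)
    q, _ = np.histogram(iv, bins=edges)
    return bhattacharyya_distance(p / p.sum(), q / q.sum())


def margin_threshold(sigma_d: float, T: int, alpha: float = 0.05) -> float:
    """M_hat = sigma_d * z_{1-alpha/2} / sqrt(T)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if sigma_d < 0 or T < 1:
        raise ValueError("need sigma_d >= 0 and T >= 1")
    return sigma_d * stats.norm.ppf(1 - alpha / 2) / np.sqrt(T)


def decide(pd_: PredictiveDistribution, alpha: float = 0.05) -> CertaintyDecision:
    """Certain iff M > M_hat; the boundary M == M_hat counts as uncertain."""
    M, sigma_d, _ = margin_of_confidence(pd_)
    th = margin_threshold(sigma_d, pd_.T, alpha)
    return CertaintyDecision(pd_.predicted_class, M, sigma_d, th, alpha, M > th)


def compute_measures(pd_: PredictiveDistribution) -> UncertaintyMeasures:
    """All five measures for one predictive distribution."""
    H, Hn = predictive_entropy(pd_)
    M, sigma_d, d = margin_of_confidence(pd_)
    return UncertaintyMeasures(
        VR=variation_ratio(pd_),
        H=H,
        Hn=Hn,
        I=mutual_information(pd_),
        Vtot=total_variance(pd_),
        M=M,
        sigma_d=sigma_d,
        d=d,
    )


def evaluate_uncertainty(decisions, true_labels) -> UncertaintyReport:
    """Four-way counting of (correct/incorrect) x (certain/uncertain)."""
    true_labels = np.asarray(true_labels)
    if len(decisions) != len(true_labels):
        raise ValueError("decisions and labels must be aligned")
    if len(decisions) == 0:
        raise ValueError("need at least one prediction")
    cc = ic = cu = iu = 0
    for dec, y in zip(decisions, true_labels):
        correct = dec.predicted_class == y
        if dec.certain:
            cc, ic = cc + correct, ic + (not correct)
        else:
            cu, iu = cu + correct, iu + (not correct)
    return UncertaintyReport(N_cc=cc, N_ic=ic, N_cu=cu, N_iu=iu)


def sweep_threshold_multiplier(
    pds: list[PredictiveDistribution],
    true_labels,
    z_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate the reject rule over a grid of threshold multipliers.

    For each z, a prediction is certain iff M > sigma_d * z / sqrt(T);
    z = 1.96 and z = 2.576 correspond to confidence levels 0.95 and 0.99.
    Returns the (z, Rc, Rcc, Riu, UA) curve and a summary with the grid
    optimum UA* and the UA at the two reference multipliers.
    """
    if z_grid is None:
        z_grid = np.geomspace(0.1, 10.0, 100)
    z_grid = np.asarray(z_grid, dtype=np.float64)
    if z_grid.size == 0:
        raise ValueError("empty multiplier grid")
    true_labels = np.asarray(true_labels)
    stats_ = np.array(
        [(p.predicted_class, *margin_of_confidence(p)[:2], p.T) for p in pds]
    )
    correct = stats_[:, 0].astype(int) == true_labels
    M, sigma_d, T = stats_[:, 1], stats_[:, 2], stats_[:, 3]

    def report_at(z: float) -> UncertaintyReport:
        certain = M > sigma_d * z / np.sqrt(T)
        return UncertaintyReport(
            N_cc=int(np.sum(correct & certain)),
            N_ic=int(np.sum(~correct & certain)),
            N_cu=int(np.sum(correct & ~certain)),
            N_iu=int(np.sum(~correct & ~certain)),
        )

    rows = []
    for z in z_grid:
        r = report_at(z)
        rows.append({"z": z, "Rc": r.Rc, "Rcc": r.Rcc, "Riu": r.Riu, "UA": r.UA})
    curve = pd.DataFrame(rows)
    i_best = int(curve["UA"].idxmax())
    z95 = stats.norm.ppf(0.975)
    z99 = stats.norm.ppf(0.995)
    summary = {
        "UA_star": float(curve["UA"].iloc[i_best]),
        "z_star": float(curve["z"].iloc[i_best]),
        "UA_at_0.95": report_at(z95).UA,
        "UA_at_0.99": report_at(z99).UA,
    }
    return curve, summary
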