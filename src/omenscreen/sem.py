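"""Latent-composite screening: the Perception-of-Dangerous-Omen score.

The measurement model has two correlated latent factors — *bioelectrical*
(five EEG band powers and the ECG feature) and *eye movement* (gaze
velocity and the two pupil diameters) — each measured by its indicators
with loadings lambda and indicator-specific error terms.  The screening
score is the linear composite

    PDO = rho1 * sum_j lambda_1j * z_j(bio) + rho2 * sum_j lambda_2j * z_j(eye)

over *standardized* features (raw-scale features span thirteen orders of
magnitude, so the composite is only meaningful on z-scores).  rho1 is
fixed at 1 for identification; rho2 weights the eye-movement factor
relative to the bioelectrical one.  Raw composites are min-max normalized
to [0, 1] on the training cohort (held-out drivers are clipped) and
thresholded: normalized PDO >= threshold (boundary inclusive) predicts D2.

Two calibration modes exist.  *Published* mode uses the reported
standardized weights and the reported decision boundary 0.3125.  *Refit*
mode estimates the loadings by maximum likelihood on the training
covariance (the estimation backend here is a scipy-based ML fit of the
confirmatory factor structure; any backend returning a standardized
solution satisfies the contract), takes rho2 as the estimated inter-factor
correlation, and tunes the decision boundary to maximise balanced
accuracy on training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from omenscreen.cohort import (
    BIO_FEATURES,
    CohortTable,
    DriverRecord,
    EYE_FEATURES,
    FEATURES,
)

__all__ = [
    "EstimationError",
    "FitIndices",
    "PdoModel",
    "ScreeningResult",
    "SemFit",
    "SemSpec",
    "calibrate",
    "compute_pdo",
    "default_sem_spec",
    "fit_indices",
    "fit_sem",
    "published_weights",
    "screen_cohort",
    "standardize_features",
]

#: Published standardized factor loadings of the screening model.
PUBLISHED_LOADINGS_BIO = {
    "alpha": 0.452, "beta": 0.123, "theta": 0.289,
    "delta": 0.511, "gamma": -0.028, "ecg": 0.015,
}
PUBLISHED_LOADINGS_EYE = {"gv": 0.008, "lpd": -0.012, "rpd": 0.035}
PUBLISHED_RHO = (1.000, 0.068)
PUBLISHED_THRESHOLD = 0.3125


class EstimationError(RuntimeError):
    """Maximum-likelihood estimation failed; carries the optimizer log."""

    def __init__(self, message: str, log: str = ""):
        super().__init__(message)
        self.log = log


@dataclass(frozen=True)
class SemSpec:
    """Measurement structure: factor name -> ordered indicator tuple."""

    factors: dict

    def __post_init__(self) -> None:
        seen = set()
        for name, indicators in self.factors.items():
            if not indicators:
                raise ValueError(f"factor {name!r} has no indicators")
            overlap = seen & set(indicators)
            if overlap:
                raise ValueError(f"indicators in several factors: {sorted(overlap)}")
            seen |= set(indicators)

    @property
    def indicators(self) -> tuple:
        return tuple(i for inds in self.factors.values() for i in inds)


def default_sem_spec() -> SemSpec:
    return SemSpec(
        factors={"bioelectrical": BIO_FEATURES, "eye_movement": EYE_FEATURES}
    )


@dataclass(frozen=True)
class SemFit:
    """Standardized ML solution of a confirmatory factor structure."""

    spec: SemSpec
    loadings: dict  # factor -> {indicator: standardized loading}
    factor_corr: float  # inter-factor correlation (1.0 for a single factor)
    error_variances: dict  # indicator -> standardized uniqueness
    implied_cov: np.ndarray
    sample_cov: np.ndarray
    discrepancy: float  # minimized ML fit function F_ML
    n_obs: int
    n_free: int
    df: int
    heywood: bool
    log: str


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    chi2_per_df: float
    rmsea: float
    cfi: float
    nfi: float
    tli: float
    gfi: float
    tli_exceeds_one: bool


@dataclass(frozen=True)
class PdoModel:
    """A calibrated, portable screening model."""

    lambda_bio: dict
    lambda_eye: dict
    rho: tuple = PUBLISHED_RHO
    standardization: dict | None = None  # feature -> (mean, sd)
    bounds: tuple | None = None  # (train min, train max) of raw PDO
    threshold: float = PUBLISHED_THRESHOLD
    mode: str = "published"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.bounds is not None and not (self.bounds[0] < self.bounds[1]):
            raise ValueError("normalization bounds must satisfy min < max")
        if self.standardization is not None:
            bad = [f for f, (_, sd) in self.standardization.items() if sd <= 0]
            if bad:
                raise ValueError(f"non-positive standardization SD for {bad}")

    @property
    def features(self) -> tuple:
        return tuple(self.lambda_bio) + tuple(self.lambda_eye)

    def is_calibrated(self) -> bool:
        return self.standardization is not None and self.bounds is not None


@dataclass(frozen=True)
class ScreeningResult:
    driver_id: str
    raw_pdo: float
    normalized_pdo: float
    predicted: str


# --------------------------------------------------------------------------
# Standardization and the composite score
# --------------------------------------------------------------------------

def standardize_features(frame, features=FEATURES):
    """Per-feature z-transform; returns (Z, params).

    ``params`` maps feature -> (training mean, training SD) and must be
    reused unchanged on held-out data.  A zero-variance feature is a
    calibration error and is named in the exception.
    """
    if isinstance(frame, CohortTable):
        frame = frame.to_frame()
    params = {}
    z = pd.DataFrame(index=frame.index)
    for f in features:
        col = frame[f].astype(float)
        mean, sd = float(col.mean()), float(col.std(ddof=1))
        if not sd > 0:
            raise ValueError(f"feature {f!r} has zero variance; cannot standardize")
        params[f] = (mean, sd)
        z[f] = (col - mean) / sd
    return z, params


def _raw_pdo(z: dict, model: PdoModel) -> float:
    rho1 = model.rho[0]
    rho2 = model.rho[1] if len(model.rho) > 1 else 0.0
    bio = sum(w * z[f] for f, w in model.lambda_bio.items())
    eye = sum(w * z[f] for f, w in model.lambda_eye.items())
    return float(rho1 * bio + rho2 * eye)


def compute_pdo(record, model: PdoModel) -> ScreeningResult:
    """Score one driver against a calibrated model.

    Accepts a :class:`DriverRecord` or a plain feature mapping carrying a
    ``driver_id`` key.  The predicted label is D2 iff the normalized score
    reaches the threshold (boundary inclusive).
    """
    if not model.is_calibrated():
        raise ValueError(
            "model is not calibrated: standardization and normalization "
            "bounds are required (see calibrate())"
        )
    if isinstance(record, DriverRecord):
        feats = record.features
        driver_id = record.driver_id
    else:
        feats = record
        driver_id = str(record.get("driver_id", ""))
    missing = [f for f in model.features if feats.get(f) is None]
    if missing:
        raise ValueError(f"driver {driver_id}: missing features {missing}")
    z = {
        f: (feats[f] - model.standardization[f][0]) / model.standardization[f][1]
        for f in model.features
    }
    raw = _raw_pdo(z, model)
    lo, hi = model.bounds
    normalized = float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))
    # boundary inclusive for D2, robust to floating-point ties
    at_boundary = math.isclose(
        normalized, model.threshold, rel_tol=1e-9, abs_tol=1e-12
    )
    predicted = "D2" if (normalized >= model.threshold or at_boundary) else "D1"
    return ScreeningResult(
        driver_id=driver_id, raw_pdo=raw, normalized_pdo=normalized,
        predicted=predicted,
    )


def screen_cohort(cohort: CohortTable, model: PdoModel) -> list:
    return [compute_pdo(r, model) for r in cohort]


def published_weights() -> PdoModel:
    """The reported standardized weights and decision boundary.

    Standardization parameters and normalization bounds are not part of
    the published report; they are supplied by :func:`calibrate`.
    """
    return PdoModel(
        lambda_bio=dict(PUBLISHED_LOADINGS_BIO),
        lambda_eye=dict(PUBLISHED_LOADINGS_EYE),
        rho=PUBLISHED_RHO,
        threshold=PUBLISHED_THRESHOLD,
        mode="published",
    )


# --------------------------------------------------------------------------
# Maximum-likelihood estimation of the factor structure
# --------------------------------------------------------------------------

def _ml_discrepancy(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        tr = float(np.trace(linalg.solve(sigma, s, assume_a="pos")))
    except linalg.LinAlgError:
        return np.inf
    return logdet + tr - logdet_s - s.shape[0]


def fit_sem(z, spec: SemSpec | None = None, n_obs: int | None = None) -> SemFit:
    """ML fit of the confirmatory factor structure on standardized data.

    Parameters
    ----------
    z : DataFrame of standardized indicators, or a sample covariance
        matrix (then ``n_obs`` is required and column order follows
        ``spec.indicators``).
    spec : SemSpec, default the two-factor bioelectrical/eye structure.

    Factor variances are fixed at 1; factors may correlate.  A factor
    with a single indicator is treated as manifest (loading 1, zero
    uniqueness).  The returned solution is fully standardized, with each
    factor's sign anchored so that its loading sum is non-negative.
    """
    spec = spec or default_sem_spec()
    indicators = list(spec.indicators)
    if isinstance(z, pd.DataFrame):
        data = z[indicators].to_numpy(dtype=float)
        n_obs = data.shape[0]
        s = np.cov(data, rowvar=False, ddof=1)
    else:
        s = np.asarray(z, dtype=float)
        if n_obs is None:
            raise ValueError("n_obs is required when passing a covariance matrix")
    p = len(indicators)
    if s.shape != (p, p):
        raise ValueError(f"covariance must be {p}x{p}, got {s.shape}")

    factors = list(spec.factors)
    blocks = {f: [indicators.index(i) for i in spec.factors[f]] for f in factors}
    multi = [f for f in factors if len(blocks[f]) >= 2]
    single = [f for f in factors if len(blocks[f]) == 1]
    two_factor = len(factors) == 2

    # free parameters: loadings of multi-indicator factors, their
    # uniquenesses (log scale), and the factor correlation (atanh scale)
    free_loadings = [(f, j) for f in multi for j in blocks[f]]
    n_free = 2 * len(free_loadings) + (1 if two_factor else 0)
    if n_obs <= n_free:
        raise ValueError(
            f"need more observations ({n_obs}) than free parameters ({n_free})"
        )

    sd = np.sqrt(np.diag(s))
    x0 = np.concatenate([
        [0.7 * sd[j] for _, j in free_loadings],
        [math.log(max(0.5 * s[j, j], 1e-4)) for _, j in free_loadings],
        [np.arctanh(0.2)] if two_factor else [],
    ])

    sign_eps = 1e-12
    logdet_s = float(np.linalg.slogdet(s)[1])

    def build(theta):
        lam = np.zeros((p, len(factors)))
        psi = np.zeros(p)
        k = len(free_loadings)
        for idx, (f, j) in enumerate(free_loadings):
            lam[j, factors.index(f)] = theta[idx]
            psi[j] = math.exp(min(theta[k + idx], 30.0))
        for f in single:
            j = blocks[f][0]
            lam[j, factors.index(f)] = sd[j]  # manifest: factor == indicator
            psi[j] = sign_eps
        phi = np.eye(len(factors))
        if two_factor:
            rho = math.tanh(theta[-1])
            phi[0, 1] = phi[1, 0] = rho
        return lam, phi, psi

    def objective(theta):
        lam, phi, psi = build(theta)
        sigma = lam @ phi @ lam.T + np.diag(psi)
        return _ml_discrepancy(sigma, s, logdet_s)

    res = optimize.minimize(objective, x0, method="L-BFGS-B")
    log = (
        f"L-BFGS-B: success={res.success}, iterations={res.nit}, "
        f"F_ML={res.fun:.6g}, message={res.message}"
    )
    if not res.success or not np.isfinite(res.fun):
        raise EstimationError("ML estimation did not converge", log=log)

    lam, phi, psi = build(res.x)
    sigma = lam @ phi @ lam.T + np.diag(psi)

    # sign anchoring: each factor oriented so its loading sum is >= 0
    flip = np.ones(len(factors))
    for fi in range(len(factors)):
        if lam[:, fi].sum() < 0:
            flip[fi] = -1.0
    lam = lam * flip
    rho = float(phi[0, 1] * flip[0] * flip[1]) if two_factor else 1.0

    implied_sd = np.sqrt(np.diag(sigma))
    std_loadings = {}
    heywood = False
    for fi, f in enumerate(factors):
        std_loadings[f] = {}
        for j in blocks[f]:
            l_std = float(lam[j, fi] / implied_sd[j])
            std_loadings[f][indicators[j]] = l_std
            if abs(l_std) > 1.0:
                heywood = True
    err_var = {}
    for j, ind in enumerate(indicators):
        ev = float(psi[j] / implied_sd[j] ** 2)
        err_var[ind] = ev
        if psi[j] <= 1e-5 and ind not in {spec.factors[f][0] for f in single}:
            heywood = True

    return SemFit(
        spec=spec,
        loadings=std_loadings,
        factor_corr=rho,
        error_variances=err_var,
        implied_cov=sigma,
        sample_cov=s,
        discrepancy=float(res.fun),
        n_obs=n_obs,
        n_free=n_free,
        df=p * (p + 1) // 2 - n_free,
        heywood=heywood,
        log=log,
    )


def fit_indices(fit: SemFit, sample_cov=None, n_obs: int | None = None) -> FitIndices:
    """Global fit indices from the ML discrepancy.

    chi2 = (N - 1) * F_ML; RMSEA = sqrt(max(chi2 - df, 0) / (df (N - 1)));
    CFI/NFI/TLI are computed against the independence baseline (all
    covariances zero); GFI is the standard ML definition.  TLI can exceed
    1 in finite samples; it is flagged, not clipped.
    """
    s = fit.sample_cov if sample_cov is None else np.asarray(sample_cov, float)
    n = fit.n_obs if n_obs is None else n_obs
    p = s.shape[0]
    df = fit.df
    chi2 = (n - 1) * fit.discrepancy

    corr = s / np.sqrt(np.outer(np.diag(s), np.diag(s)))
    f_base = -float(np.linalg.slogdet(corr)[1])
    chi2_b = (n - 1) * f_base
    df_b = p * (p - 1) // 2

    if df > 0:
        rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
        chi2_per_df = chi2 / df
    else:
        rmsea, chi2_per_df = 0.0, float("nan")

    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)
    nfi = (chi2_b - chi2) / chi2_b if chi2_b > 0 else 1.0
    if df > 0 and df_b > 0 and chi2_b / df_b != 1.0:
        tli = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
    else:
        tli = 1.0
    sinv_s = linalg.solve(fit.implied_cov, s, assume_a="pos")
    resid = sinv_s - np.eye(p)
    gfi = 1.0 - float(np.trace(resid @ resid)) / float(np.trace(sinv_s @ sinv_s))

    return FitIndices(
        chi2=float(chi2), df=df, chi2_per_df=float(chi2_per_df),
        rmsea=float(rmsea), cfi=float(cfi), nfi=float(nfi), tli=float(tli),
        gfi=float(gfi), tli_exceeds_one=bool(tli > 1.0),
    )


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def _balanced_accuracy(scores, truth, cut):
    pred_d2 = scores >= cut
    is_d2 = truth == "D2"
    tpr = pred_d2[is_d2].mean() if is_d2.any() else 0.0
    tnr = (~pred_d2[~is_d2]).mean() if (~is_d2).any() else 0.0
    return (tpr + tnr) / 2.0


def _tune_threshold(norm_scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision boundary maximizing balanced accuracy; plateau -> midpoint."""
    uniq = np.unique(norm_scores)
    cand = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([0.5])
    cand = cand[(cand > 0.0) & (cand < 1.0)]
    if cand.size == 0:
        cand = np.array([0.5])
    scores = np.array([_balanced_accuracy(norm_scores, labels, c) for c in cand])
    best = scores.max()
    optimal = cand[scores >= best - 1e-12]
    mid = float((optimal[0] + optimal[-1]) / 2.0)
    if _balanced_accuracy(norm_scores, labels, mid) >= best - 1e-12:
        return mid
    return float(optimal[optimal.size // 2])


def calibrate(
    cohort: CohortTable,
    mode: str = "published",
    features=FEATURES,
) -> PdoModel:
    """Calibrate a screening model on a labeled training cohort.

    Standardization parameters and the min-max normalization bounds of the
    raw composite are always estimated here (on training data only).
    ``mode="published"`` keeps the reported weights and the reported
    boundary 0.3125; ``mode="refit"`` re-estimates the loadings by ML on
    the training covariance, sets rho2 to the estimated inter-factor
    correlation, and tunes the boundary for balanced accuracy.

    ``features`` restricts the model to a subset of indicators (ablation
    support); a side with a single indicator degrades to that standardized
    feature with weight 1.
    """
    if mode not in ("published", "refit"):
        raise ValueError(f"mode must be 'published' or 'refit', got {mode!r}")
    labels = np.array(cohort.labels())
    if not ({"D1", "D2"} <= set(labels)):
        raise ValueError("calibration requires both D1 and D2 drivers")
    bio = tuple(f for f in BIO_FEATURES if f in features)
    eye = tuple(f for f in EYE_FEATURES if f in features)
    if not bio and not eye:
        raise ValueError("feature subset is empty")

    frame = cohort.to_frame()
    used = bio + eye
    z, params = standardize_features(frame, features=used)

    if mode == "published":
        lam_bio = {f: PUBLISHED_LOADINGS_BIO[f] for f in bio}
        lam_eye = {f: PUBLISHED_LOADINGS_EYE[f] for f in eye}
        rho = PUBLISHED_RHO if (bio and eye) else (1.0, 0.0)
    else:
        lam_bio, lam_eye, rho2 = _refit_weights(z, bio, eye)
        rho = (1.0, rho2)

    interim = PdoModel(
        lambda_bio=lam_bio, lambda_eye=lam_eye, rho=rho,
        standardization=params,
        bounds=(-1.0, 1.0),  # placeholder, replaced below
        threshold=0.5, mode=mode,
    )
    raw = np.array(
        [_raw_pdo({f: z.loc[i, f] for f in used}, interim) for i in z.index]
    )
    lo, hi = float(raw.min()), float(raw.max())
    if not lo < hi:
        raise ValueError("degenerate training scores: all raw PDO values equal")
    if mode == "published":
        threshold = PUBLISHED_THRESHOLD
    else:
        threshold = _tune_threshold((raw - lo) / (hi - lo), labels)
    return PdoModel(
        lambda_bio=lam_bio, lambda_eye=lam_eye, rho=rho,
        standardization=params, bounds=(lo, hi), threshold=threshold, mode=mode,
    )


def _refit_weights(z: pd.DataFrame, bio: tuple, eye: tuple):
    """Refit-mode weights for a (possibly ablated) indicator set."""
    blocks = {}
    if bio:
        blocks["bioelectrical"] = bio
    if eye:
        blocks["eye_movement"] = eye

    if len(blocks) == 2 and all(len(b) >= 2 for b in blocks.values()):
        fit = fit_sem(z, SemSpec(factors=blocks))
        return (
            dict(fit.loadings["bioelectrical"]),
            dict(fit.loadings["eye_movement"]),
            fit.factor_corr,
        )

    def block_weights(names):
        if len(names) == 1:
            return {names[0]: 1.0}
        fit = fit_sem(z, SemSpec(factors={"f": names}))
        return dict(fit.loadings["f"])

    w_bio = block_weights(bio) if bio else {}
    w_eye = block_weights(eye) if eye else {}
    if w_bio and w_eye:
        score_bio = sum(w * z[f] for f, w in w_bio.items())
        score_eye = sum(w * z[f] for f, w in w_eye.items())
        rho2 = float(np.corrcoef(score_bio, score_eye)[0, 1])
    elif w_eye and not w_bio:
        # eye-only model: the single remaining path carries weight 1
        w_bio, w_eye, rho2 = w_eye, {}, 0.0
    else:
        rho2 = 0.0
    return w_bio, w_eye, rho2
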