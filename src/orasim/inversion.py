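"""Response-surface inversion: sweep, quadratic regression, published equations.

The forward pipeline (mechanics -> optics -> features) maps six inputs
(R, CCT, IOP, E, a1, tau1) to the ORA output parameters (w1, w2, p1, p2).
This module samples that map over the physiological ranges, fits a multiple
quadratic regression of the biomechanical parameters on the normalized
observables, validates it on a held-out split, and also evaluates the
published closed-form inversion equations verbatim:

    E  = 2.5 E0 [0.323 - 0.030 R* - 0.018 IOP* - 0.034 w1* - 0.078 w2* + 0.230 p2*]
    a1 = 0.298 - 0.055 R* - 0.104 IOP* - 0.679 w1* + 0.330 w2* + 0.536 p1*
         - 0.380 p2* + 0.330 w1*^2 + 0.075 p2*^2
    lg(tau1/tau10) = -5.419 + 0.017 R* - 0.033 CCT* - 0.013 w1* + 0.140 w2*
         - 0.086 p1* - 0.165 p2*

where starred quantities are normalized by the cohort-mean constants
(E0 = 0.4 MPa, tau10 = 0.001 s, R0 = 7 mm, IOP0 = 15 mmHg, w10 = 10,
w20 = 17, p10 = 10 mmHg, p20 = 5 mmHg; CCT0 = 550 um).

Note: the published tau1 equation has an intercept (-5.419) that is
inconsistent with the tau1 magnitude it is reported to produce on the same
cohort (lg(tau1/tau10) ~ +0.5); it is nevertheless evaluated verbatim.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .units import um_to_mm  # noqa: F401  (re-exported convenience)

__all__ = [
    "SweepRanges",
    "NormalizationConstants",
    "InversionModel",
    "InversionFit",
    "BiomechanicalParams",
    "sample_parameters",
    "run_sweep",
    "fit_inversion",
    "validate_inversion",
    "predict_biomechanics",
    "invert_published",
    "published_models",
    "relaxation_limit",
    "save_models",
    "load_models",
]

MODEL_SCHEMA_VERSION = 1

LINEAR_TERMS = ("R", "CCT", "IOP", "w1", "w2", "p1", "p2")

_COLUMN_OF = {
    "R": "R_mm", "CCT": "CCT_um", "IOP": "IOP_mmHg",
    "w1": "w1", "w2": "w2", "p1": "p1_mmHg", "p2": "p2_mmHg",
}


@dataclass(frozen=True)
class NormalizationConstants:
    """Cohort-mean constants used to make regression inputs dimensionless."""

    E0_MPa: float = 0.4
    tau10_s: float = 0.001
    R0_mm: float = 7.0
    IOP0_mmHg: float = 15.0
    w10: float = 10.0
    w20: float = 17.0
    p10_mmHg: float = 10.0
    p20_mmHg: float = 5.0
    CCT0_um: float = 550.0

    def __post_init__(self):
        if min(asdict(self).values()) <= 0:
            raise ValueError("normalization constants must be positive")

    def scale_of(self, term: str) -> float:
        return {"R": self.R0_mm, "CCT": self.CCT0_um, "IOP": self.IOP0_mmHg,
                "w1": self.w10, "w2": self.w20, "p1": self.p10_mmHg,
                "p2": self.p20_mmHg}[term]


@dataclass(frozen=True)
class SweepRanges:
    """Uniform sampling ranges of the six swept parameters.

    a2, a3 and tau2, tau3 are held fixed across the sweep.
    """

    R_mm: tuple[float, float] = (6.0, 8.0)
    CCT_um: tuple[float, float] = (450.0, 650.0)
    IOP_mmHg: tuple[float, float] = (10.0, 30.0)
    E_MPa: tuple[float, float] = (0.2, 0.6)
    a1: tuple[float, float] = (0.25, 0.6)
    tau1_s: tuple[float, float] = (0.001, 0.1)
    a2: float = 0.1
    a3: float = 0.1
    tau2_s: float = 1.0e-4
    tau3_s: float = 1.0e-4
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self):
        for name in ("R_mm", "CCT_um", "IOP_mmHg", "E_MPa", "a1", "tau1_s"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name} must have lower < upper")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass(frozen=True)
class BiomechanicalParams:
    """Inverted corneal biomechanical parameters."""

    E_MPa: float
    a1: float
    tau1_s: float
    G_inf: float


def relaxation_limit(a1: float, a2: float = 0.1, a3: float = 0.1) -> float:
    """Long-time relaxation plateau ``G_inf = 1 - a1 - a2 - a3``."""
    if min(a1, a2, a3) < 0:
        raise ValueError("Prony moduli must be nonnegative")
    s = a1 + a2 + a3
    if s >= 1.0:
        raise ValueError("Prony moduli must sum to less than 1")
    return 1.0 - s


def sample_parameters(ranges: SweepRanges) -> pd.DataFrame:
    """Uniform independent samples of the six swept parameters.

    Reproducible under a fixed seed; one row per simulation.
    """
    rng = np.random.default_rng(ranges.seed)
    cols = {}
    for name in ("R_mm", "CCT_um", "IOP_mmHg", "E_MPa", "a1", "tau1_s"):
        lo, hi = getattr(ranges, name)
        cols[name] = rng.uniform(lo, hi, ranges.n_samples)
    return pd.DataFrame(cols)


def run_sweep(samples: pd.DataFrame, config=None, progress: bool = False,
              max_failure_fraction: float = 0.2) -> pd.DataFrame:
    """Forward-simulate every sample row and collect the feature table.

    Failed rows are kept with ``status`` describing the failure; the sweep
    aborts only if more than ``max_failure_fraction`` of rows fail.
    """
    from .pipeline import SimulationConfig, simulate_ora

    if config is None:
        config = SimulationConfig()
    records = []
    for idx, row in samples.reset_index(drop=True).iterrows():
        rec = {k: float(row[k]) for k in
               ("R_mm", "CCT_um", "IOP_mmHg", "E_MPa", "a1", "tau1_s")}
        try:
            feats = simulate_ora(rec["R_mm"], rec["CCT_um"], rec["IOP_mmHg"],
                                 rec["E_MPa"], rec["a1"], rec["tau1_s"], config)
            rec.update(t1_s=feats.t1_s, t2_s=feats.t2_s,
                       w1=feats.w1, w2=feats.w2,
                       p1_mmHg=feats.p1_mmHg, p2_mmHg=feats.p2_mmHg,
                       status="ok")
        except Exception as exc:  # per-row failure is data, not fatal
            rec.update(t1_s=np.nan, t2_s=np.nan, w1=np.nan, w2=np.nan,
                       p1_mmHg=np.nan, p2_mmHg=np.nan,
                       status=f"{type(exc).__name__}: {exc}")
        records.append(rec)
        if progress:
            print(f"[sweep] {idx + 1}/{len(samples)} {rec['status']}")
    table = pd.DataFrame(records)
    n_fail = int((table["status"] != "ok").sum())
    if len(table) and n_fail / len(table) > max_failure_fraction:
        raise RuntimeError(
            f"{n_fail}/{len(table)} sweep rows failed "
            f"(> {max_failure_fraction:.0%}); first failure: "
            f"{table.loc[table['status'] != 'ok', 'status'].iloc[0]}")
    return table


# ---------------------------------------------------------------------------
# regression basis and models
# ---------------------------------------------------------------------------

def basis_terms(kind: str = "quadratic") -> list[str]:
    """Term names of the normalized polynomial basis."""
    terms = ["1", *LINEAR_TERMS]
    if kind == "linear":
        return terms
    if kind == "quadratic":
        return terms + [f"{t}^2" for t in LINEAR_TERMS]
    if kind == "full":
        out = terms + [f"{t}^2" for t in LINEAR_TERMS]
        for i, a in enumerate(LINEAR_TERMS):
            for b in LINEAR_TERMS[i + 1:]:
                out.append(f"{a}*{b}")
        return out
    raise ValueError(f"unknown basis kind {kind!r}")


def _normalized_predictors(df: pd.DataFrame, const: NormalizationConstants
                           ) -> pd.DataFrame:
    out = {}
    for term in LINEAR_TERMS:
        out[term] = np.asarray(df[_COLUMN_OF[term]], dtype=float) / const.scale_of(term)
    return pd.DataFrame(out)


def _design_matrix(norm: pd.DataFrame, terms: list[str]) -> np.ndarray:
    n = len(norm)
    X = np.empty((n, len(terms)))
    for j, term in enumerate(terms):
        if term == "1":
            X[:, j] = 1.0
        elif term.endswith("^2"):
            X[:, j] = norm[term[:-2]] ** 2
        elif "*" in term:
            a, b = term.split("*")
            X[:, j] = norm[a] * norm[b]
        else:
            X[:, j] = norm[term]
    return X


@dataclass
class InversionModel:
    """One target's regression over the normalized polynomial basis.

    The regression response is a dimensionless transform of the target
    (``E / (2.5 E0)``, ``a1`` itself, or ``lg(tau1/tau10)``); ``predict``
    undoes the transform.
    """

    target: str                      # "E" | "a1" | "lgtau1"
    terms: list[str]
    coefficients: np.ndarray
    constants: NormalizationConstants = field(default_factory=NormalizationConstants)
    provenance: str = "fitted"       # "fitted" | "published"
    seed: int | None = None

    def evaluate_basis(self, features: pd.DataFrame) -> np.ndarray:
        norm = _normalized_predictors(features, self.constants)
        return _design_matrix(norm, self.terms) @ np.asarray(self.coefficients)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        y = self.evaluate_basis(features)
        if self.target == "E":
            return 2.5 * self.constants.E0_MPa * y
        if self.target == "a1":
            return y
        if self.target == "lgtau1":
            return self.constants.tau10_s * 10.0 ** y
        raise ValueError(f"unknown target {self.target!r}")

    def response(self, table: pd.DataFrame) -> np.ndarray:
        """Transform raw target columns into the regression response."""
        if self.target == "E":
            return np.asarray(table["E_MPa"], float) / (2.5 * self.constants.E0_MPa)
        if self.target == "a1":
            return np.asarray(table["a1"], float)
        if self.target == "lgtau1":
            return np.log10(np.asarray(table["tau1_s"], float) / self.constants.tau10_s)
        raise ValueError(f"unknown target {self.target!r}")


_PUBLISHED = {
    "E": {"1": 0.323, "R": -0.030, "IOP": -0.018,
          "w1": -0.034, "w2": -0.078, "p2": 0.230},
    "a1": {"1": 0.298, "R": -0.055, "IOP": -0.104, "w1": -0.679, "w2": 0.330,
           "p1": 0.536, "p2": -0.380, "w1^2": 0.330, "p2^2": 0.075},
    "lgtau1": {"1": -5.419, "R": 0.017, "CCT": -0.033, "w1": -0.013,
               "w2": 0.140, "p1": -0.086, "p2": -0.165},
}


def published_models(constants: NormalizationConstants | None = None
                     ) -> dict[str, InversionModel]:
    """The published inversion equations as fixed coefficient sets."""
    const = constants or NormalizationConstants()
    out = {}
    for target, coeffs in _PUBLISHED.items():
        out[target] = InversionModel(
            target=target, terms=list(coeffs),
            coefficients=np.array(list(coeffs.values())),
            constants=const, provenance="published")
    return out


def _warn_out_of_range(name: str, value, lo: float, hi: float) -> None:
    v = np.asarray(value, dtype=float)
    if np.any((v < lo) | (v > hi)):
        warnings.warn(f"{name} outside the calibrated sweep range [{lo}, {hi}]",
                      stacklevel=3)


def invert_published(R_mm, CCT_um, IOP_mmHg, w1, w2, p1_mmHg, p2_mmHg,
                     constants: NormalizationConstants | None = None):
    """Biomechanical parameters from the published closed-form equations.

    Accepts scalars or equal-length arrays.  Inputs outside the sweep
    ranges trigger a warning (clinical cohorts sit near the range edges),
    not an error; nonpositive inputs are rejected.
    """
    vals = dict(R_mm=R_mm, CCT_um=CCT_um, IOP_mmHg=IOP_mmHg,
                w1=w1, w2=w2, p1_mmHg=p1_mmHg, p2_mmHg=p2_mmHg)
    for name, v in vals.items():
        if np.any(np.asarray(v, dtype=float) <= 0):
            raise ValueError(f"{name} must be positive")
    rng = SweepRanges()
    _warn_out_of_range("R_mm", R_mm, *rng.R_mm)
    _warn_out_of_range("CCT_um", CCT_um, *rng.CCT_um)
    _warn_out_of_range("IOP_mmHg", IOP_mmHg, *rng.IOP_mmHg)

    df = pd.DataFrame({_COLUMN_OF[k]: np.atleast_1d(np.asarray(v, dtype=float))
                       for k, v in
                       [("R", R_mm), ("CCT", CCT_um), ("IOP", IOP_mmHg),
                        ("w1", w1), ("w2", w2), ("p1", p1_mmHg), ("p2", p2_mmHg)]})
    models = published_models(constants)
    E = models["E"].predict(df)
    a1 = models["a1"].predict(df)
    tau1 = models["lgtau1"].predict(df)
    ginf = 1.0 - a1 - 0.2  # a2 = a3 = 0.1 fixed
    scalar = np.isscalar(R_mm)
    if scalar:
        return BiomechanicalParams(float(E[0]), float(a1[0]),
                                   float(tau1[0]), float(ginf[0]))
    return pd.DataFrame({"E_MPa": E, "a1": a1, "tau1_s": tau1, "G_inf": ginf})


# ---------------------------------------------------------------------------
# fitting and validation
# ---------------------------------------------------------------------------

@dataclass
class InversionFit:
    """Fitted inversion models plus the train/test bookkeeping."""

    models: dict[str, InversionModel]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    heldout_predictions: pd.DataFrame


def _collinear_terms(X: np.ndarray, terms: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = diag.max() * max(X.shape) * np.finfo(float).eps
    return [terms[piv[i]] for i in range(len(terms)) if diag[i] < thresh]


def _backward_eliminate(X: np.ndarray, y: np.ndarray, terms: list[str],
                        p_threshold: float):
    import statsmodels.api as sm

    keep = list(range(len(terms)))
    while len(keep) > 1:
        res = sm.OLS(y, X[:, keep]).fit()
        pvals = res.pvalues.copy()
        for i, idx in enumerate(keep):
            if terms[idx] == "1":
                pvals[i] = -1.0  # never drop the intercept
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_threshold:
            break
        keep.pop(worst)
    return keep


def fit_inversion(
    table: pd.DataFrame,
    split: float = 0.7,
    seed: int = 0,
    basis: str = "quadratic",
    eliminate: bool = False,
    p_threshold: float = 0.05,
    constants: NormalizationConstants | None = None,
    min_rows: int = 30,
) -> InversionFit:
    """Least-squares fit of (E, a1, lg tau1) on the normalized basis.

    A random ``split`` fraction of usable rows trains each model; the rest
    is held out and its predictions are returned for validation.  Optional
    backward elimination drops terms with p-values above ``p_threshold``.
    """
    const = constants or NormalizationConstants()
    usable = table[table["status"] == "ok"] if "status" in table else table
    usable = usable.dropna(subset=["w1", "w2", "p1_mmHg", "p2_mmHg"])
    if len(usable) < min_rows:
        raise ValueError(f"need at least {min_rows} usable rows, got {len(usable)}")
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie strictly between 0 and 1 "
                         "(the held-out set must be nonempty)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usable))
    n_train = int(round(split * len(usable)))
    n_train = min(max(n_train, 1), len(usable) - 1)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    train = usable.iloc[train_idx]
    test = usable.iloc[test_idx]

    terms = basis_terms(basis)
    norm_train = _normalized_predictors(train, const)
    X = _design_matrix(norm_train, terms)

    models: dict[str, InversionModel] = {}
    preds = {}
    for target in ("E", "a1", "lgtau1"):
        proto = InversionModel(target=target, terms=terms,
                               coefficients=np.zeros(len(terms)),
                               constants=const, seed=seed)
        y = proto.response(train)
        use_terms, Xt = terms, X
        if eliminate:
            keep = _backward_eliminate(X, y, terms, p_threshold)
            use_terms = [terms[i] for i in keep]
            Xt = X[:, keep]
        coef, _, rank, _ = np.linalg.lstsq(Xt, y, rcond=None)
        if rank < Xt.shape[1]:
            bad = _collinear_terms(Xt, use_terms)
            raise np.linalg.LinAlgError(
                f"rank-deficient design for target {target}; "
                f"collinear terms: {bad or 'unresolved'}")
        model = InversionModel(target=target, terms=list(use_terms),
                               coefficients=coef, constants=const, seed=seed)
        models[target] = model
        preds[target] = model.predict(test)

    heldout = test.copy()
    heldout["E_MPa_pred"] = preds["E"]
    heldout["a1_pred"] = preds["a1"]
    heldout["tau1_s_pred"] = preds["lgtau1"]
    return InversionFit(models=models, train_idx=train_idx, test_idx=test_idx,
                        seed=seed, heldout_predictions=heldout)


def validate_inversion(models: dict[str, InversionModel] | InversionFit,
                       test_rows: pd.DataFrame) -> dict[str, dict]:
    """Held-out metrics (R^2, RMSE, raw pairs) per target."""
    if isinstance(models, InversionFit):
        models = models.models
    if len(test_rows) == 0:
        raise ValueError("empty test set")
    out = {}
    for target, model in models.items():
        truth = {"E": "E_MPa", "a1": "a1", "lgtau1": "tau1_s"}[target]
        y_true = np.asarray(test_rows[truth], dtype=float)
        y_pred = np.asarray(model.predict(test_rows), dtype=float)
        if target == "lgtau1":  # compare on the fitted (log) scale
            y_true = np.log10(y_true)
            y_pred = np.log10(y_pred)
        resid = y_true - y_pred
        ss_res = float(np.sum(resid ** 2))
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
        out[target] = {
            "r2": r2,
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "pairs": np.column_stack([y_true, y_pred]),
        }
    return out


def predict_biomechanics(models: dict[str, InversionModel] | InversionFit,
                         features: pd.DataFrame) -> pd.DataFrame:
    """Apply fitted (or published) models to a subject feature table."""
    if isinstance(models, InversionFit):
        models = models.models
    E = models["E"].predict(features)
    a1 = models["a1"].predict(features)
    tau1 = models["lgtau1"].predict(features)
    return pd.DataFrame({"E_MPa": E, "a1": a1, "tau1_s": tau1,
                         "G_inf": 1.0 - a1 - 0.2})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_models(models: dict[str, InversionModel] | InversionFit, path) -> None:
    if isinstance(models, InversionFit):
        payload_extra = {"train_idx": models.train_idx.tolist(),
                         "test_idx": models.test_idx.tolist(),
                         "seed": models.seed}
        models = models.models
    else:
        payload_extra = {}
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "constants": asdict(next(iter(models.values())).constants),
        "models": {
            t: {"terms": m.terms, "coefficients": np.asarray(m.coefficients).tolist(),
                "provenance": m.provenance, "seed": m.seed}
            for t, m in models.items()
        },
        **payload_extra,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_models(path) -> dict[str, InversionModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError("unsupported model schema version")
    const = NormalizationConstants(**payload["constants"])
    out = {}
    for target, m in payload["models"].items():
        out[target] = InversionModel(
            target=target, terms=list(m["terms"]),
            coefficients=np.array(m["coefficients"], dtype=float),
            constants=const, provenance=m.get("provenance", "fitted"),
            seed=m.get("seed"))
    return out
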