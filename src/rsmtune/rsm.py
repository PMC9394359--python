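"""Quadratic response-surface fitting and ANOVA diagnostics on coded factors.

The response surface is the full second-order polynomial in coded factor
levels,

    Y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2 + e,

fitted by ordinary least squares. Two-level categorical factors enter as a
single ±1 column (first level −1, second +1) with no squared term, since a
two-level contrast squared is constant. Diagnostics follow standard
response-surface practice: partial (Type III) sums of squares per term,
residual split into lack of fit and pure error over replicate groups, the
R²/adjusted-R²/predicted-R² family with PRESS computed from leverages, and the
adequate-precision signal-to-noise ratio.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .doe import DesignMatrix, FactorSpec, decode_value

__all__ = [
    "TransformSpec",
    "SurfaceModel",
    "AnovaRow",
    "AnovaTable",
    "SingularDesignError",
    "apply_transform",
    "invert_transform",
    "scan_transform",
    "fit_quadratic",
    "predict",
    "anova",
    "find_optimum",
]

_ALLOWED_LAMBDAS = (-1.0, 0.0, 0.5, 1.0)


class SingularDesignError(np.linalg.LinAlgError):
    """The model matrix is rank deficient; some terms are aliased."""


@dataclass(frozen=True)
class TransformSpec:
    """Box-Cox power transform of the response.

    ``lam`` is restricted to the four standard choices: −1 (inverse),
    0 (natural log), 0.5 (square root) and 1 (identity).
    """

    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.lam not in _ALLOWED_LAMBDAS:
            raise ValueError(f"lambda must be one of {_ALLOWED_LAMBDAS}, got {self.lam}")


def apply_transform(y, t: TransformSpec) -> np.ndarray:
    """Transform responses: 1/y, ln y, sqrt y, or identity depending on lambda."""
    y = np.asarray(y, dtype=float)
    if t.lam != 1.0 and np.any(y <= 0):
        bad = int(np.flatnonzero(y <= 0)[0])
        raise ValueError(
            f"lambda={t.lam} requires strictly positive responses; "
            f"run index {bad} has value {y[bad]}"
        )
    if t.lam == -1.0:
        return 1.0 / y
    if t.lam == 0.0:
        return np.log(y)
    if t.lam == 0.5:
        return np.sqrt(y)
    return y.copy()


def invert_transform(z, t: TransformSpec) -> np.ndarray:
    """Inverse of :func:`apply_transform`."""
    z = np.asarray(z, dtype=float)
    if t.lam == -1.0:
        return 1.0 / z
    if t.lam == 0.0:
        return np.exp(z)
    if t.lam == 0.5:
        return z ** 2
    return z.copy()


# ---------------------------------------------------------------------------
# model terms and matrices

Term = tuple[str, ...]  # () intercept, (a,) linear, (a, b) interaction, (a, a) square


def _term_label(term: Term) -> str:
    if not term:
        return "Intercept"
    if len(term) == 1:
        return term[0]
    a, b = term
    return f"{a}^2" if a == b else f"{a}*{b}"


def _canonical_terms(factors: tuple[FactorSpec, ...]) -> list[Term]:
    """Intercept, linear terms, all two-factor interactions, numeric squares."""
    names = [f.name for f in factors]
    terms: list[Term] = [()]
    terms += [(n,) for n in names]
    terms += [tuple(p) for p in itertools.combinations(names, 2)]
    terms += [(f.name, f.name) for f in factors if f.is_numeric]
    return terms


def _coded_columns(factors: tuple[FactorSpec, ...], design: DesignMatrix) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for f in factors:
        if f.is_numeric:
            cols[f.name] = design.coded[f.name].to_numpy(dtype=float)
        else:
            if len(f.levels) != 2:
                raise ValueError(
                    f"model fitting supports two-level categorical factors only; "
                    f"{f.name!r} has {len(f.levels)} levels"
                )
            labels = design.table[f.name].to_numpy()
            cols[f.name] = np.where(labels == f.levels[0], -1.0, 1.0)
    return cols


def _model_matrix(terms: list[Term], cols: dict[str, np.ndarray], n: int) -> np.ndarray:
    X = np.empty((n, len(terms)))
    for j, term in enumerate(terms):
        col = np.ones(n)
        for name in term:
            col = col * cols[name]
        X[:, j] = col
    return X


@dataclass
class SurfaceModel:
    """A fitted coded quadratic surface: ordered terms, one coefficient per term,
    the response transform, and the factor specs that define the coding."""

    factors: tuple[FactorSpec, ...]
    terms: list[Term]
    coefficients: np.ndarray
    transform: TransformSpec

    def coef(self, *term: str) -> float:
        """Coefficient of a term given by factor name(s), e.g. ``coef("neurons")``
        or ``coef("neurons", "neurons")`` for the squared term."""
        key = tuple(term)
        for t, c in zip(self.terms, self.coefficients):
            if t == key or t == key[::-1]:
                return float(c)
        raise KeyError(f"no term {key} in model")

    @property
    def intercept(self) -> float:
        return self.coef()

    def term_labels(self) -> list[str]:
        return [_term_label(t) for t in self.terms]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.term_labels(), "coefficient": self.coefficients}
        )


def fit_quadratic(design: DesignMatrix, transform: TransformSpec = TransformSpec(0.0)) -> SurfaceModel:
    """Fit the full quadratic surface to a design's responses by least squares.

    The response is transformed first; coefficients are on the transformed
    scale per coded unit. Raises :class:`SingularDesignError` when the model
    matrix is rank deficient (aliased terms are named).
    """
    if not design.has_responses:
        raise ValueError("design has no responses to fit")
    factors = design.spec.factors
    terms = _canonical_terms(factors)
    cols = _coded_columns(factors, design)
    X = _model_matrix(terms, cols, len(design))
    if len(design) < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} runs to fit {X.shape[1]} terms, have {len(design)}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the terms involved in the null space of X
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        involved = sorted(
            {_term_label(terms[j]) for j in np.flatnonzero(np.abs(null).max(axis=0) > 1e-8)}
        )
        raise SingularDesignError(f"design is singular; aliased terms: {involved}")
    z = apply_transform(design.responses, transform)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return SurfaceModel(factors=factors, terms=terms, coefficients=beta, transform=transform)


def predict(model: SurfaceModel, point: dict) -> float:
    """Evaluate the fitted surface at one point (transformed response scale).

    ``point`` maps factor names to coded levels for numeric factors and to a
    level label (or ±1 code) for categorical factors.
    """
    vals: dict[str, float] = {}
    for f in model.factors:
        if f.name not in point:
            raise KeyError(f"point is missing factor {f.name!r}")
        v = point[f.name]
        if f.is_numeric:
            vals[f.name] = float(v)
            if abs(vals[f.name]) > 1.0 + 1e-9:
                warnings.warn(
                    f"coded level {vals[f.name]} for {f.name!r} is outside the design "
                    "region; the prediction is an extrapolation",
                    stacklevel=2,
                )
        else:
            if isinstance(v, str):
                if v not in f.levels:
                    raise ValueError(f"unknown level {v!r} for factor {f.name!r}")
                vals[f.name] = -1.0 if v == f.levels[0] else 1.0
            else:
                vals[f.name] = float(v)
    out = 0.0
    for term, c in zip(model.terms, model.coefficients):
        prod = 1.0
        for name in term:
            prod *= vals[name]
        out += c * prod
    return float(out)


# ---------------------------------------------------------------------------
# ANOVA

@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    """Per-term partial-SS ANOVA with lack-of-fit decomposition and the
    response-surface adequacy statistics."""

    model: AnovaRow
    terms: list[AnovaRow]
    residual: AnovaRow
    lack_of_fit: AnovaRow | None
    pure_error: AnovaRow | None
    cor_total: AnovaRow
    r2: float
    adjusted_r2: float
    predicted_r2: float
    press: float
    adequate_precision: float

    def rows(self) -> list[AnovaRow]:
        out = [self.model, *self.terms, self.residual]
        if self.lack_of_fit is not None:
            out.append(self.lack_of_fit)
        if self.pure_error is not None:
            out.append(self.pure_error)
        out.append(self.cor_total)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "sum_of_squares": r.ss,
                    "df": r.df,
                    "mean_square": r.ms,
                    "f_value": r.f,
                    "p_value": r.p,
                }
                for r in self.rows()
            ]
        )

    def to_json(self, **kwargs) -> str:
        payload = {
            "rows": self.to_frame().to_dict(orient="records"),
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "predicted_r2": self.predicted_r2,
            "press": self.press,
            "adequate_precision": self.adequate_precision,
        }
        return json.dumps(payload, **kwargs)

    def format_text(self) -> str:
        """Aligned text table in the conventional Model / terms / Residual /
        Lack of Fit / Pure Error / Cor Total layout."""

        def fmt_p(p):
            if p is None:
                return ""
            return "<0.0001" if p < 1e-4 else f"{p:.4f}"

        def fmt(v, nd=4):
            return "" if v is None else f"{v:.{nd}f}"

        lines = [
            f"{'Source':<16}{'SS':>10}{'df':>5}{'MS':>10}{'F':>10}{'p':>10}"
        ]
        for r in self.rows():
            lines.append(
                f"{r.source:<16}{fmt(r.ss):>10}{r.df:>5}{fmt(r.ms):>10}"
                f"{fmt(r.f, 2):>10}{fmt_p(r.p):>10}"
            )
        lines.append("")
        lines.append(f"{'R^2':<20}{self.r2:.4f}")
        lines.append(f"{'Adjusted R^2':<20}{self.adjusted_r2:.4f}")
        lines.append(f"{'Predicted R^2':<20}{self.predicted_r2:.4f}")
        lines.append(f"{'Adeq. precision':<20}{self.adequate_precision:.4f}")
        return "\n".join(lines)


def _pure_error(design: DesignMatrix, z: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df pooled over replicate groups (runs with identical
    actual factor settings)."""
    keys = design.table[[f.name for f in design.spec.factors]].astype(str).agg("|".join, axis=1)
    ss = 0.0
    df = 0
    for _, idx in keys.groupby(keys).groups.items():
        g = z[np.asarray(idx)]
        if len(g) > 1:
            ss += float(((g - g.mean()) ** 2).sum())
            df += len(g) - 1
    return ss, df


def anova(model: SurfaceModel, design: DesignMatrix, ss_type: str = "partial") -> AnovaTable:
    """Full ANOVA of a fitted surface on its design.

    Per-term sums of squares are partial (Type III) by default: the SS of a
    term is the increase in residual SS when that term alone is dropped.
    ``ss_type="sequential"`` gives Type I SS in canonical term order instead
    (identical on orthogonal designs). F ratios use the residual mean square;
    lack of fit is tested against pure error pooled from replicate runs.
    """
    if ss_type not in ("partial", "sequential"):
        raise ValueError("ss_type must be 'partial' or 'sequential'")
    cols = _coded_columns(model.factors, design)
    n = len(design)
    X = _model_matrix(model.terms, cols, n)
    z = apply_transform(design.responses, model.transform)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    zhat = X @ beta
    resid = z - zhat

    ss_res = float(resid @ resid)
    ss_tot = float(((z - z.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    p_count = X.shape[1]
    df_model = p_count - 1
    df_res = n - p_count
    df_tot = n - 1
    ms_res = ss_res / df_res if df_res > 0 else math.nan
    ms_model = ss_model / df_model
    f_model = ms_model / ms_res
    p_model = float(stats.f.sf(f_model, df_model, df_res))

    term_rows: list[AnovaRow] = []
    non_intercept = [j for j, t in enumerate(model.terms) if t]
    if ss_type == "partial":
        for j in non_intercept:
            Xr = np.delete(X, j, axis=1)
            br, *_ = np.linalg.lstsq(Xr, z, rcond=None)
            ss_j = float(((z - Xr @ br) ** 2).sum()) - ss_res
            term_rows.append(_term_row(model.terms[j], ss_j, ms_res, df_res))
    else:
        prev_sse = ss_tot
        for m in range(len(non_intercept)):
            Xs = X[:, [0] + non_intercept[: m + 1]]
            bs, *_ = np.linalg.lstsq(Xs, z, rcond=None)
            sse = float(((z - Xs @ bs) ** 2).sum())
            term_rows.append(_term_row(model.terms[non_intercept[m]], prev_sse - sse, ms_res, df_res))
            prev_sse = sse

    ss_pe, df_pe = _pure_error(design, z)
    if df_pe > 0:
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe
        if df_lof > 0 and ms_pe > 0:
            ms_lof = ss_lof / df_lof
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        elif df_lof > 0:
            # replicates agree exactly; the lack-of-fit ratio is undefined
            ms_lof, f_lof, p_lof = ss_lof / df_lof, None, None
        else:
            ms_lof, f_lof, p_lof = None, None, None
        lof_row = AnovaRow("Lack of Fit", ss_lof, df_lof, ms_lof, f_lof, p_lof)
        pe_row = AnovaRow("Pure Error", ss_pe, df_pe, ms_pe)
    else:
        lof_row = None
        pe_row = None

    # leverages for PRESS
    h = np.einsum("ij,ij->i", X @ np.linalg.inv(X.T @ X), X)
    press = float((((resid) / (1.0 - h)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / df_tot)
    pred_r2 = 1.0 - press / ss_tot
    adeq = float((zhat.max() - zhat.min()) / math.sqrt(p_count * ms_res / n))

    return AnovaTable(
        model=AnovaRow("Model", ss_model, df_model, ms_model, f_model, p_model),
        terms=term_rows,
        residual=AnovaRow("Residual", ss_res, df_res, ms_res),
        lack_of_fit=lof_row,
        pure_error=pe_row,
        cor_total=AnovaRow("Cor Total", ss_tot, df_tot),
        r2=r2,
        adjusted_r2=adj_r2,
        predicted_r2=pred_r2,
        press=press,
        adequate_precision=adeq,
    )


def _term_row(term: Term, ss: float, ms_res: float, df_res: int) -> AnovaRow:
    f = ss / ms_res
    return AnovaRow(_term_label(term), ss, 1, ss, f, float(stats.f.sf(f, 1, df_res)))


def scan_transform(design: DesignMatrix, lambdas=_ALLOWED_LAMBDAS) -> tuple[TransformSpec, pd.DataFrame]:
    """Box-Cox scan: fit the quadratic under each candidate lambda and score it
    by the profile log-likelihood (residual SS of the Jacobian-scaled response).
    Returns the best transform and the per-lambda score table."""
    y = design.responses
    if np.any(y <= 0):
        raise ValueError("Box-Cox scan requires strictly positive responses")
    n = len(y)
    gm = float(np.exp(np.mean(np.log(y))))
    records = []
    for lam in lambdas:
        t = TransformSpec(lam)
        z = apply_transform(y, t)
        # Jacobian scaling makes SSE comparable across lambdas
        if lam == 0.0:
            zs = z * gm
        elif lam == -1.0:
            zs = z * gm ** 2  # |d(1/y)/dy| = y^-2
        else:
            zs = z / (lam * gm ** (lam - 1.0))
        m = fit_quadratic(design.with_responses(y), t)
        cols = _coded_columns(m.factors, design)
        X = _model_matrix(m.terms, cols, n)
        bs, *_ = np.linalg.lstsq(X, zs, rcond=None)
        sse = float(((zs - X @ bs) ** 2).sum())
        llf = -0.5 * n * math.log(sse / n)
        records.append({"lambda": lam, "scaled_sse": sse, "loglik": llf})
    table = pd.DataFrame.from_records(records)
    best = float(table.loc[table["loglik"].idxmax(), "lambda"])
    return TransformSpec(best), table


# ---------------------------------------------------------------------------
# optimum search

def _eval_surface(model: SurfaceModel, grids: dict[str, np.ndarray], cat_codes: dict[str, float]) -> np.ndarray:
    out = np.zeros(next(iter(grids.values())).shape)
    for term, c in zip(model.terms, model.coefficients):
        prod = np.ones_like(out) * c
        for name in term:
            prod = prod * (grids[name] if name in grids else cat_codes[name])
        out += prod
    return out


def find_optimum(model: SurfaceModel, goal: str = "minimize", grid_step: float = 0.05):
    """Locate the surface optimum over the coded cube [−1, 1]^k.

    For each categorical level combination the surface is evaluated on a dense
    grid (step ``grid_step``) and the best grid point is polished with bounded
    L-BFGS-B. Returns ``(best, per_level)`` where each entry carries the coded
    point, the categorical levels, and the predicted (transformed-scale)
    response. Deterministic.
    """
    if goal not in ("minimize", "maximize"):
        raise ValueError("goal must be 'minimize' or 'maximize'")
    sign = 1.0 if goal == "minimize" else -1.0
    numeric = [f for f in model.factors if f.is_numeric]
    categorical = [f for f in model.factors if not f.is_numeric]
    axes = np.arange(-1.0, 1.0 + 1e-12, grid_step)
    mesh = np.meshgrid(*[axes] * len(numeric), indexing="ij")
    grids = {f.name: m for f, m in zip(numeric, mesh)}

    combos = list(itertools.product(*[f.levels for f in categorical])) or [()]
    per_level = []
    for combo in combos:
        cat_codes = {
            f.name: (-1.0 if lev == f.levels[0] else 1.0)
            for f, lev in zip(categorical, combo)
        }
        vals = sign * _eval_surface(model, grids, cat_codes)
        flat = int(np.argmin(vals))
        x0 = np.array([g.ravel()[flat] for g in mesh])

        def objective(x):
            point = dict(zip((f.name for f in numeric), x))
            point.update(cat_codes)
            return sign * predict(model, point)

        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=[(-1.0, 1.0)] * len(numeric)
        )
        x = res.x if res.fun <= vals.ravel()[flat] else x0
        coded = dict(zip((f.name for f in numeric), map(float, x)))
        point = dict(coded)
        point.update(dict(zip((f.name for f in categorical), combo)))
        per_level.append(
            {
                "categorical": dict(zip((f.name for f in categorical), combo)),
                "coded": coded,
                "actual": {f.name: decode_value(f, coded[f.name]) for f in numeric},
                "predicted": predict(model, point),
            }
        )
    best = min(per_level, key=lambda r: sign * r["predicted"])
    return best, per_level
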