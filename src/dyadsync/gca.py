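"""Growth-curve analysis of diagonal recurrence profiles.

The recurrence rate ``RR`` of dyad *d* at lag *t* is modelled with a
linear mixed-effects model over orthogonal lag polynomials::

    RR ~ (c + k + l + q)**full-factorial   (16 fixed effects)

where ``c`` is conversation type (affiliative 0 / argumentative 1),
``k`` task condition (dual-task 0 / noise 1), ``l`` and ``q`` the first-
and second-order orthonormal polynomials over the lag window.  Random
intercepts for dyad and for conversation number (nested in dyad) are
always present; random slopes are chosen by backward selection from a
candidate set until the model converges without a singular fit.

The module is organised statsmodels-style: :class:`DRPGrowthModel` is
built from an assembled long-format table and ``fit()`` returns a
:class:`DRPGrowthResults` carrying estimates, standard errors, t- and
p-values (normal approximation), the random-effect structure and the
backward-selection attempt log.  Convenience fitters
(:func:`fit_full_model`, :func:`fit_posthoc_models`,
:func:`fit_baseline_contrast_models`) mirror the analyses reported for
this design: the full model, per-conversation-type post-hoc models, and
real-vs-surrogate contrast models with a ``data`` factor coded -0.5
(surrogate baseline) / +0.5 (real).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "orthogonal_lag_polynomials",
    "assemble_gca_table",
    "DRPGrowthModel",
    "DRPGrowthResults",
    "fit_full_model",
    "fit_posthoc_models",
    "fit_baseline_contrast_models",
]

# (column name, label, factor columns) for the full factorial expansion
_FACTOR_LABEL = {"c": "conversation", "k": "task", "l": "ll", "q": "ql", "d": "data"}

FULL_TERMS: List[Tuple[str, ...]] = [
    ("c",), ("k",), ("l",), ("q",),
    ("c", "k"), ("l", "q"), ("c", "l"), ("k", "l"), ("k", "c", "l"),
    ("c", "q"), ("k", "q"), ("k", "c", "q"),
    ("c", "l", "q"), ("k", "l", "q"), ("k", "c", "l", "q"),
]

POSTHOC_TERMS: List[Tuple[str, ...]] = [
    ("k",), ("l",), ("q",), ("l", "q"), ("k", "l"), ("k", "q"), ("k", "l", "q"),
]

#: default random-slope candidates: the within-dyad-varying slope structure
#: retained in this design's reference specification
DEFAULT_SLOPE_CANDIDATES: Tuple[str, ...] = ("c", "l", "q", "kcl")

_SINGULAR_VAR = 1e-8


def _colname(factors: Tuple[str, ...]) -> str:
    return "".join(factors)


def _label(factors: Tuple[str, ...]) -> str:
    return ":".join(_FACTOR_LABEL[f] for f in factors)


def orthogonal_lag_polynomials(lags: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """First- and second-order orthonormal polynomials over the lag grid.

    Gram-Schmidt orthonormalization of (1, lag, lag^2): the linear term
    is odd-symmetric in lag, the quadratic even-symmetric, both unit
    norm and mutually orthogonal.
    """
    lg = np.asarray(lags, dtype=float)
    if len(np.unique(lg)) < 3:
        raise ValueError("need at least 3 distinct lags")
    X = np.column_stack([np.ones_like(lg), lg, lg**2])
    Q, R = np.linalg.qr(X)
    l = Q[:, 1] * np.sign(R[1, 1])
    q = Q[:, 2] * np.sign(R[2, 2])
    return l, q


def assemble_gca_table(drp: pd.DataFrame) -> pd.DataFrame:
    """Join DRP rows with condition codes and orthogonal lag terms.

    ``drp`` is the long-format DRP table with columns ``dyad``,
    ``conversation`` (conversation number), ``conv_type``, ``task``,
    ``lag``, ``rr`` and optionally ``source``/``surrogate_id``.  Every
    unit (dyad x conversation x source x surrogate) must cover the full
    common lag grid exactly once.  When both real and surrogate rows are
    present a ``d`` column codes the data factor (-0.5 surrogate,
    +0.5 real).
    """
    df = drp.copy()
    required = {"dyad", "conversation", "conv_type", "task", "lag", "rr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DRP table missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "real"
    if "surrogate_id" not in df.columns:
        df["surrogate_id"] = 0
    df["surrogate_id"] = df["surrogate_id"].fillna(0).astype(int)

    lag_grid = np.sort(df["lag"].unique())
    unit_cols = ["dyad", "conversation", "source", "surrogate_id"]
    for unit, g in df.groupby(unit_cols):
        lags = g["lag"].to_numpy()
        if len(np.unique(lags)) != len(lags):
            raise ValueError(f"duplicate lag in unit {unit}")
        if len(lags) != len(lag_grid) or not np.array_equal(np.sort(lags), lag_grid):
            raise ValueError(
                f"unit {unit} does not cover the full lag grid "
                f"({len(lags)} of {len(lag_grid)} lags)"
            )
    l, q = orthogonal_lag_polynomials(lag_grid)
    poly = pd.DataFrame({"lag": lag_grid, "l": l, "q": q})
    out = df.merge(poly, on="lag", how="left")
    bad_conv = set(out["conv_type"]) - {"affiliative", "argumentative"}
    if bad_conv:
        raise ValueError(f"unknown conversation types: {sorted(bad_conv)}")
    bad_task = set(out["task"]) - {"dual-task", "noise"}
    if bad_task:
        raise ValueError(f"unknown task conditions: {sorted(bad_task)}")
    out["c"] = (out["conv_type"] == "argumentative").astype(float)
    out["k"] = (out["task"] == "noise").astype(float)
    if out["source"].nunique() > 1:
        out["d"] = np.where(out["source"] == "real", 0.5, -0.5)
    out = out.rename(columns={"conversation": "convnum"})
    # orthonormality is a structural invariant of every assembled table
    assert abs(float(np.dot(l, q))) < 1e-10
    assert abs(float(np.dot(l, l)) - 1) < 1e-10 and abs(float(np.dot(q, q)) - 1) < 1e-10
    return out


@dataclass
class _Attempt:
    step: int
    slopes: Tuple[str, ...]
    converged: bool
    singular: bool
    error: Optional[str]
    dropped: Optional[str]

    def as_dict(self) -> Dict:
        return {
            "step": self.step,
            "slopes": list(self.slopes),
            "converged": self.converged,
            "singular": self.singular,
            "error": self.error,
            "dropped": self.dropped,
        }


class DRPGrowthModel:
    """Mixed-effects growth-curve model of a DRP table.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`assemble_gca_table` (columns ``rr``, ``dyad``,
        ``convnum``, ``c``, ``k``, ``l``, ``q`` and optionally ``d``).
    terms : sequence of factor tuples
        The fixed-effect expansion; defaults to the 16-term full
        factorial.  Terms whose columns do not vary in ``table`` (e.g.
        ``k`` in a single-task subset) are dropped with a note.
    include_data : bool
        Add the ``data`` factor and its interactions with every term
        (real-vs-baseline contrast models).
    standardized : bool
        z-score the outcome and every predictor column, so estimates
        read as effect sizes.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        terms: Optional[Sequence[Tuple[str, ...]]] = None,
        include_data: bool = False,
        standardized: bool = False,
    ):
        self.table = table
        self.standardized = standardized
        self.include_data = include_data
        base_terms = list(terms) if terms is not None else list(FULL_TERMS)
        if include_data:
            if "d" not in table.columns or table["d"].nunique() < 2:
                raise ValueError(
                    "the data factor needs both real and surrogate rows; "
                    "got a single level"
                )
            expanded = list(base_terms) + [("d",)] + [t + ("d",) for t in base_terms]
        else:
            expanded = base_terms
        self.dropped_terms: List[str] = []
        self._terms: List[Tuple[str, ...]] = []
        data = pd.DataFrame(
            {
                "dyad": table["dyad"].astype(str),
                "convnum": table["convnum"].astype(int),
                "rr": table["rr"].astype(float),
            }
        )
        for t in expanded:
            col = table[list(t)].prod(axis=1).to_numpy(dtype=float)
            name = _colname(t)
            if np.ptp(col) == 0:
                self.dropped_terms.append(_label(t))
                continue
            data[name] = col
            self._terms.append(t)
        if standardized:
            data["rr"] = (data["rr"] - data["rr"].mean()) / data["rr"].std()
            for t in self._terms:
                cn = _colname(t)
                data[cn] = (data[cn] - data[cn].mean()) / data[cn].std()
        self.data = data
        self.term_names = [_colname(t) for t in self._terms]
        self.term_labels = ["intercept"] + [_label(t) for t in self._terms]
        # in a single-conversation-per-dyad subset (post-hoc models) the
        # conversation-number intercept is confounded with the dyad
        # intercept and its variance is not identified
        self.convnum_identified = bool(
            (data.groupby("dyad")["convnum"].nunique() > 1).any()
        )

    @classmethod
    def from_drp_table(
        cls,
        drp: pd.DataFrame,
        standardized: bool = False,
        include_data: Optional[bool] = None,
        terms: Optional[Sequence[Tuple[str, ...]]] = None,
    ) -> "DRPGrowthModel":
        """Build directly from a long-format DRP table (assembles codes
        and polynomials first).  ``include_data`` defaults to True when
        both real and surrogate rows are present."""
        table = assemble_gca_table(drp)
        if include_data is None:
            include_data = "d" in table.columns
        return cls(table, terms=terms, include_data=include_data, standardized=standardized)

    # -- fitting ------------------------------------------------------

    def _fit_once(self, slopes: Sequence[str], reml: bool, maxiter: int):
        fixed = "rr ~ " + " + ".join(self.term_names) if self.term_names else "rr ~ 1"
        re_formula = "1" + "".join(f" + {s}" for s in slopes)
        vc = {}
        if self.convnum_identified:
            vc["convnum"] = "0 + C(convnum)"
            for s in slopes:
                vc[f"convnum_{s}"] = f"0 + C(convnum):{s}"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = MixedLM.from_formula(
                fixed, data=self.data, groups="dyad",
                re_formula=re_formula, vc_formula=vc or None,
            )
            # boundary-variance fits stall under gradient methods; fall
            # through a deterministic optimizer cascade
            res = None
            for method in ("lbfgs", "powell", "cg"):
                caught.clear()
                res = model.fit(
                    reml=reml, method=method,
                    maxiter=500 if maxiter is None else maxiter,
                )
                if res.converged:
                    break
            # an indefinite Hessian marks an ill-conditioned optimum;
            # with random slopes present it disqualifies the fit
            bad_hessian = any(
                "not positive definite" in str(w.message) for w in caught
            )
        return model, res, bad_hessian

    def _slope_variances(self, model, res, slopes: Sequence[str]) -> Dict[str, float]:
        out: Dict[str, float] = {}
        cov = res.cov_re
        for s in slopes:
            v = float(cov.loc[s, s]) if s in cov.index else 0.0
            for name, vcv in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
                if name == f"convnum_{s}":
                    v += float(vcv)
            out[s] = v
        return out

    def fit(
        self,
        random_slopes: Union[str, Sequence[str]] = "backward",
        candidate_slopes: Optional[Sequence[str]] = None,
        reml: bool = True,
        maxiter: Optional[int] = None,
    ) -> "DRPGrowthResults":
        """Fit by REML, with backward selection of random slopes.

        ``random_slopes`` may be ``"backward"`` (start from
        ``candidate_slopes`` and drop until convergence), ``"none"``
        (random intercepts only), or an explicit list of slope column
        names applied to both grouping factors.
        """
        if isinstance(random_slopes, str):
            if random_slopes == "none":
                candidates: List[str] = []
                backward = False
            elif random_slopes == "backward":
                cand = candidate_slopes if candidate_slopes is not None else DEFAULT_SLOPE_CANDIDATES
                candidates = [s for s in cand if s in self.term_names]
                backward = True
            else:
                raise ValueError(f"unknown random_slopes mode {random_slopes!r}")
        else:
            candidates = [s for s in random_slopes if s in self.term_names]
            backward = False

        attempts: List[_Attempt] = []
        slopes = list(candidates)
        step = 0
        while True:
            err = None
            model = res = None
            bad_hessian = False
            try:
                model, res, bad_hessian = self._fit_once(slopes, reml, maxiter)
            except Exception as e:  # noqa: BLE001 - optimizer/linalg failures drive selection
                err = f"{type(e).__name__}: {e}"
            converged = bool(res is not None and res.converged)
            singular = False
            if converged and slopes:
                variances = self._slope_variances(model, res, slopes)
                singular = any(v < _SINGULAR_VAR for v in variances.values())
                singular = singular or bad_hessian
            ok = converged and not singular
            dropped = None
            if not ok and slopes and backward:
                # drop highest-interaction-order first; within an order,
                # the slope with the smallest estimated variance
                order = {s: len(s) for s in slopes}
                top = max(order.values())
                pool = [s for s in slopes if order[s] == top]
                if res is not None:
                    variances = self._slope_variances(model, res, slopes)
                    dropped = min(pool, key=lambda s: (variances.get(s, 0.0), s))
                else:
                    dropped = sorted(pool)[-1]
            attempts.append(_Attempt(step, tuple(slopes), converged, singular, err, dropped))
            if ok:
                break
            if dropped is not None:
                slopes.remove(dropped)
                step += 1
                continue
            if not slopes:
                raise RuntimeError(
                    "intercept-only model failed to converge; attempt log: "
                    + "; ".join(str(a.as_dict()) for a in attempts)
                )
            # explicit slope list that fails: report rather than silently trim
            raise RuntimeError(
                f"model with random slopes {slopes} did not converge "
                f"(converged={converged}, singular={singular}, error={err})"
            )
        return DRPGrowthResults(self, model, res, tuple(slopes), [a.as_dict() for a in attempts])


class DRPGrowthResults:
    """Fitted growth-curve model: coefficients, uncertainty, diagnostics."""

    def __init__(self, model: DRPGrowthModel, sm_model, sm_result, retained_slopes, attempt_log):
        self.model = model
        self._sm_model = sm_model
        self._sm_result = sm_result
        self.retained_slopes: Tuple[str, ...] = tuple(retained_slopes)
        self.attempt_log: List[Dict] = attempt_log
        self.standardized = model.standardized
        labels = model.term_labels
        fe = sm_result.fe_params
        self.params = pd.Series(np.asarray(fe), index=labels)
        self.bse = pd.Series(np.asarray(sm_result.bse_fe), index=labels)
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.norm.sf(np.abs(self.tvalues.to_numpy())), index=labels
        )

    @property
    def converged(self) -> bool:
        return bool(self._sm_result.converged)

    @property
    def scale(self) -> float:
        """Residual variance."""
        return float(self._sm_result.scale)

    @property
    def cov_re(self) -> pd.DataFrame:
        """Dyad-level random-effect covariance (intercept + slopes)."""
        return self._sm_result.cov_re

    @property
    def vcomp(self) -> pd.Series:
        """Conversation-number variance components."""
        return pd.Series(
            np.atleast_1d(self._sm_result.vcomp), index=self._sm_model.exog_vc.names
        )

    def random_effects(self):
        """Per-dyad deviations (intercepts and retained slopes)."""
        return self._sm_result.random_effects

    def coef_frame(self, model_name: str = "full") -> pd.DataFrame:
        """Tidy coefficient table: model, term, estimate, se, t, p."""
        return pd.DataFrame(
            {
                "model": model_name,
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "DRP growth-curve mixed model"
            + (" (standardized)" if self.standardized else ""),
            f"  observations: {len(self.model.data)}   dyads: {self.model.data['dyad'].nunique()}",
            f"  converged: {self.converged}   residual var: {self.scale:.6g}",
            f"  retained random slopes: {list(self.retained_slopes) or 'intercepts only'}",
        ]
        if self.model.dropped_terms:
            lines.append(f"  dropped constant terms: {self.model.dropped_terms}")
        lines.append("")
        lines.append(f"  {'term':<28}{'estimate':>12}{'se':>10}{'t':>9}{'p':>10}")
        for term in self.params.index:
            star = "***" if self.pvalues[term] < 0.001 else (
                "*" if self.pvalues[term] < 0.05 else ""
            )
            lines.append(
                f"  {term:<28}{self.params[term]:>12.4f}{self.bse[term]:>10.4f}"
                f"{self.tvalues[term]:>9.2f}{self.pvalues[term]:>10.4f} {star}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DRPGrowthResults converged={self.converged} n={len(self.model.data)}>"


# -- convenience fitters ---------------------------------------------------


def fit_full_model(
    drp_or_table: pd.DataFrame,
    standardized: bool = True,
    random_slopes: Union[str, Sequence[str]] = "backward",
    **fit_kw,
) -> DRPGrowthResults:
    """The 16-term full-factorial model on real-data DRP rows."""
    table = _as_table(drp_or_table)
    table = table[table["source"] == "real"] if "source" in table.columns else table
    model = DRPGrowthModel(table, standardized=standardized)
    return model.fit(random_slopes=random_slopes, **fit_kw)


def fit_posthoc_models(
    drp_or_table: pd.DataFrame,
    standardized: bool = True,
    random_slopes: Union[str, Sequence[str]] = "backward",
    include_data: bool = False,
    **fit_kw,
) -> Dict[str, DRPGrowthResults]:
    """Separate models per conversation type (task, ll, ql and their
    interactions), mirroring the post-hoc decomposition of the full model."""
    table = _as_table(drp_or_table)
    if not include_data and "source" in table.columns:
        table = table[table["source"] == "real"]
    user_cand = fit_kw.pop("candidate_slopes", None)
    out: Dict[str, DRPGrowthResults] = {}
    for conv in ("affiliative", "argumentative"):
        sub = table[table["conv_type"] == conv]
        if sub.empty:
            continue
        model = DRPGrowthModel(
            sub, terms=POSTHOC_TERMS, include_data=include_data, standardized=standardized
        )
        cand = user_cand if user_cand is not None else tuple(
            s for s in ("l", "q") if s in model.term_names
        )
        out[conv] = model.fit(
            random_slopes=random_slopes, candidate_slopes=cand, **fit_kw
        )
    return out


def fit_baseline_contrast_models(
    drp_or_table: pd.DataFrame,
    standardized: bool = True,
    random_slopes: Union[str, Sequence[str]] = "backward",
    posthoc: bool = True,
    **fit_kw,
) -> Dict[str, DRPGrowthResults]:
    """Real-vs-surrogate contrast models: the data factor (-0.5 baseline,
    +0.5 real) and its interactions join the full and post-hoc formulas."""
    table = _as_table(drp_or_table)
    if "d" not in table.columns:
        raise ValueError(
            "contrast models need both real and surrogate rows in the DRP table"
        )
    model = DRPGrowthModel(table, include_data=True, standardized=standardized)
    out = {"full": model.fit(random_slopes=random_slopes, **fit_kw)}
    if posthoc:
        ph = fit_posthoc_models(
            table, standardized=standardized, random_slopes=random_slopes,
            include_data=True, **fit_kw,
        )
        out.update(ph)
    return out


def _as_table(df: pd.DataFrame) -> pd.DataFrame:
    """Accept either a raw DRP long table or an assembled GCA table."""
    if {"c", "k", "l", "q"}.issubset(df.columns):
        return df
    return assemble_gca_table(df)
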