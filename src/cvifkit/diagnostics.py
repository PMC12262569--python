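"""Collinearity diagnostics for first-level designs: efficiency, tVIF, cVIF.

For a contrast vector ``c`` over the columns of a design ``X`` fit by OLS,
``Var(c b^) = c (X'X)^{-1} c' sigma^2``.  Three design-only diagnostics are
provided:

* ``efficiency`` — ``1 / (c (X'X)^{-1} c')``; ranks designs, no absolute scale.
* ``tvif`` — the traditional variance inflation factor of one coefficient:
  its variance in the full model divided by its variance in a model holding
  only an intercept and that regressor.
* ``cvif`` — a contrast-based VIF.  The contrast's *effective regressor*
  ``x_c = X_task c' / (c c')`` carries the condition signal whose amplitude
  the contrast measures; the full model is reparameterized as
  ``[x_c, Z, nuisance, intercept]`` with ``Z`` spanning the image under X of
  the contrast's null space, so the coefficient of ``x_c`` *is* ``c b``.
  cVIF is the variance of that coefficient in the full model divided by its
  variance in the best-case model containing only an intercept and ``x_c``.
  For an elementary contrast (a single unit weight) this reduces exactly to
  the tVIF of that column.  Unlike tVIF, cVIF is sensitive to overlap
  between condition *signals*, which survives any reparameterization of the
  design (e.g. serial orthogonalization): pass the condition-parameterized
  design as ``condition_design`` to evaluate a reparameterized model's
  contrast against the condition signals it estimates.

Nuisance columns (drift, motion, intercept) always stay in the full model
and never enter the reduced comparison model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix

__all__ = [
    "ContrastSpec",
    "VifReport",
    "SingularDesignError",
    "efficiency",
    "tvif",
    "cvif",
    "parse_contrast",
    "vif_report",
]

#: Working flag thresholds for contrast VIFs: above 5 inspect the data for
#: outliers; above 20 the inflation is considered excessive.
CVIF_INSPECT = 5.0
CVIF_EXCESSIVE = 20.0

#: Condition number beyond which a cross-product matrix is treated as
#: singular rather than merely ill-conditioned.
_COND_LIMIT = 1e10


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when a design is (numerically) rank deficient."""


@dataclass(frozen=True)
class ContrastSpec:
    """A named weight vector aligned to design columns."""

    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("contrast weights must be a vector")
        if not np.any(w != 0):
            raise ValueError(f"contrast {self.name!r} has all-zero weights")
        object.__setattr__(self, "weights", w)

    def aligned(self, design: DesignMatrix) -> np.ndarray:
        if len(self.weights) != len(design.column_names):
            raise ValueError(
                f"contrast {self.name!r} has {len(self.weights)} weights for a "
                f"{len(design.column_names)}-column design"
            )
        return self.weights


def _xtx_inv(X: np.ndarray, context: str = "design") -> np.ndarray:
    xtx = X.T @ X
    if np.linalg.cond(xtx) > _COND_LIMIT:
        raise SingularDesignError(
            f"{context} is singular or near-singular "
            f"(condition number of X'X exceeds {_COND_LIMIT:g})"
        )
    return np.linalg.inv(xtx)


def efficiency(design: DesignMatrix, contrast: ContrastSpec) -> float:
    """Contrast efficiency ``1 / (c (X'X)^{-1} c')`` for the full design."""
    c = contrast.aligned(design)
    inv = _xtx_inv(design.values)
    return float(1.0 / (c @ inv @ c))


def _reduced_variance(x: np.ndarray) -> float:
    """Unit-noise variance of the slope in ``y = b0 + b1 x + e``."""
    ss = float(np.sum((x - x.mean()) ** 2))
    if ss <= 0:
        raise SingularDesignError("reduced-model regressor is constant")
    return 1.0 / ss


def _require_intercept(design: DesignMatrix) -> None:
    X = design.values
    const = (X.std(axis=0) == 0) & (X.mean(axis=0) != 0)
    if not const.any():
        raise ValueError("VIFs require an intercept column in the design")


def tvif(design: DesignMatrix, column: str) -> float:
    """Traditional VIF of one coefficient.

    Ratio of ``Var(b^_j)`` in the full design to ``Var(b^_j)`` in the
    two-column design (intercept + that regressor).  Equals 1 when the
    centered regressor is orthogonal to all other centered columns.
    """
    _require_intercept(design)
    if column not in design.column_names:
        raise KeyError(f"column {column!r} not in design")
    j = design.column_names.index(column)
    inv = _xtx_inv(design.values, context=f"full design (while computing tVIF of {column!r})")
    full_var = inv[j, j]
    red_var = _reduced_variance(design.values[:, j])
    return float(full_var / red_var)


def cvif(
    design: DesignMatrix,
    contrast: ContrastSpec,
    condition_design: DesignMatrix | None = None,
) -> float:
    """Contrast-based VIF.

    When ``condition_design`` is given, ``design`` is understood as a
    reparameterization of it spanning the same column space; the contrast
    is mapped onto the condition parameterization (where its effective
    regressor is a combination of condition signals) and the cVIF is
    computed there.  The estimated quantity and its full-model variance
    are identical in both parameterizations.
    """
    c_full = contrast.aligned(design)
    if condition_design is not None:
        return cvif(condition_design, _map_to_conditions(design, contrast, condition_design))
    _require_intercept(design)
    X = design.values
    inv = _xtx_inv(X)
    full_var = float(c_full @ inv @ c_full)

    task_idx = [design.column_names.index(n) for n in design.task_columns]
    off_task = np.ones(len(c_full), dtype=bool)
    off_task[task_idx] = False
    if np.any(np.abs(c_full[off_task]) > 1e-10 * np.abs(c_full).max()):
        raise ValueError(
            f"contrast {contrast.name!r} puts weight on non-task columns; "
            "cVIF is defined for contrasts of task regressors"
        )
    c_task = c_full[task_idx]
    x_c = X[:, task_idx] @ c_task / float(c_task @ c_task)
    red_var = _reduced_variance(x_c)
    return float(full_var / red_var)


def _map_to_conditions(
    design: DesignMatrix, contrast: ContrastSpec, condition_design: DesignMatrix
) -> ContrastSpec:
    """Express a contrast of ``design`` in condition-design coordinates.

    The OLS estimate ``c b^`` equals ``l'Y`` with ``l = X (X'X)^{-1} c'``;
    ``l`` depends only on the estimable quantity, not the parameterization,
    so the equivalent condition-space contrast is ``l' X_cond (X'X)_cond^{-1}
    X_cond' ...`` i.e. simply ``c_cond = l' X_cond`` whenever the two designs
    span the same space.
    """
    X = design.values
    Xc = condition_design.values
    ell = X @ (_xtx_inv(X) @ contrast.aligned(design))
    proj = Xc @ np.linalg.lstsq(Xc, ell, rcond=None)[0]
    if not np.allclose(proj, ell, atol=1e-8 * max(1.0, float(np.abs(ell).max()))):
        raise ValueError(
            "designs do not span the same space; the contrast is not "
            "estimable in the condition parameterization"
        )
    weights = ell @ Xc
    weights[np.abs(weights) < 1e-10 * np.abs(weights).max()] = 0.0
    return ContrastSpec(name=contrast.name, weights=weights)


_TERM_RE = re.compile(
    r"\s*(?P<sign>[+-])?\s*(?:(?P<coef>\d+(?:\.\d*)?|\.\d+)\s*[*x×]?\s*)?(?P<name>[A-Za-z_][\w:.-]*)"
)


def parse_contrast(expression: str, column_names: list[str], name: str | None = None) -> ContrastSpec:
    """Parse a signed weighted sum of column names into a contrast.

    Accepts expressions like ``"CueLW - CueNeut"`` or
    ``".5*A + .5*B - .5*C - .5*D"``.  Unnamed columns get weight 0.
    """
    weights = np.zeros(len(column_names))
    pos = 0
    matched = False
    while pos < len(expression):
        m = _TERM_RE.match(expression, pos)
        if m is None:
            if expression[pos:].strip():
                raise ValueError(f"cannot parse contrast expression at {expression[pos:]!r}")
            break
        matched = True
        sign = -1.0 if m.group("sign") == "-" else 1.0
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        term = m.group("name")
        if term not in column_names:
            close = [c for c in column_names if term.lower() in c.lower() or c.lower() in term.lower()]
            raise ValueError(
                f"unknown column {term!r} in contrast expression; "
                f"did you mean one of {close or column_names}?"
            )
        weights[column_names.index(term)] += sign * coef
        pos = m.end()
    if not matched:
        raise ValueError(f"empty contrast expression {expression!r}")
    return ContrastSpec(name=name or expression.strip(), weights=weights)


@dataclass
class VifReport:
    """Aggregated design diagnostics for a set of contrasts."""

    efficiency: dict[str, float]
    cvif: dict[str, float]
    tvif: dict[str, float]
    flags: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": name,
                "efficiency": self.efficiency[name],
                "cvif": self.cvif[name],
                "flag": self.flags[name],
            }
            for name in self.cvif
        ]
        return pd.DataFrame(rows)

    def tvif_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"column": k, "tvif": v} for k, v in self.tvif.items()]
        )


def vif_report(
    design: DesignMatrix,
    contrasts: list[ContrastSpec],
    candidate_columns: list[str] | None = None,
) -> VifReport:
    """Compute efficiency, cVIF and per-column tVIFs for a design.

    ``candidate_columns`` optionally lists the task regressors of a fuller
    model under consideration; any that are absent from this design are
    reported as model-comparison warnings (their signal, if real, biases
    the remaining estimates rather than showing up in any VIF).
    """
    eff = {c.name: efficiency(design, c) for c in contrasts}
    cv = {c.name: cvif(design, c) for c in contrasts}
    tv = {col: tvif(design, col) for col in design.task_columns}
    flags = {}
    for name, value in cv.items():
        if value > CVIF_EXCESSIVE:
            flags[name] = f"excessive (cVIF > {CVIF_EXCESSIVE:g})"
        elif value > CVIF_INSPECT:
            flags[name] = f"inspect (cVIF > {CVIF_INSPECT:g})"
        else:
            flags[name] = ""
    warnings = []
    for col in candidate_columns or []:
        if col not in design.column_names:
            warnings.append(
                f"regressor {col!r} omitted from this design: VIFs cannot reflect "
                "it and real signal in it would bias remaining estimates "
                "(model-comparison warning)"
            )
    return VifReport(efficiency=eff, cvif=cv, tvif=tv, flags=flags, warnings=warnings)
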