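"""Design specifications and (standard / expanded) design matrices.

A design is given by a small formula grammar, ``"~ factorA + factorB +
factorA:factorB"``.  Categorical columns of the sample metadata become
factors, numeric columns become continuous covariates.

Two kinds of design matrices are produced:

* **standard** — intercept plus base-level (treatment) coding, full
  rank; used for dispersion estimation, for the MLE fits that feed the
  LFC-prior width, and whenever interaction terms are present with all
  factors at two levels.
* **expanded** — intercept plus one indicator column for *every* level
  of each factor (no level absorbed into the intercept).  This matrix
  is rank deficient, but the ridge fit with a zero-centered prior on
  all non-intercept columns has a unique solution, and it makes the
  shrinkage symmetric across levels so contrasts do not depend on which
  level is declared the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "DesignMatrix", "build_design", "contrast_vector"]


@dataclass
class DesignSpec:
    """Parsed model formula.

    ``factors`` maps factor name -> ordered list of levels (first level
    is the base level for standard coding); ``covariates`` are numeric
    columns entering linearly; ``interactions`` are pairs of factor
    names.
    """

    factors: dict[str, list[str]] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_formula(cls, formula: str, sample_info: pd.DataFrame) -> "DesignSpec":
        formula = formula.strip()
        if formula.startswith("~"):
            formula = formula[1:]
        terms = [t.strip() for t in formula.split("+") if t.strip()]
        if not terms:
            raise ValueError("design formula must contain at least one term")
        spec = cls()
        for term in terms:
            if term == "1":
                continue
            if ":" in term:
                a, b = (x.strip() for x in term.split(":", 1))
                spec.interactions.append((a, b))
                continue
            if term not in sample_info.columns:
                raise ValueError(f"term {term!r} not found in sample metadata")
            col = sample_info[term]
            if pd.api.types.is_numeric_dtype(col):
                spec.covariates.append(term)
            else:
                levels = list(pd.unique(col.astype(str)))
                spec.factors[term] = levels
        for a, b in spec.interactions:
            for name in (a, b):
                if name not in spec.factors:
                    raise ValueError(
                        f"interaction term references {name!r}, which is not a "
                        "categorical factor in the formula"
                    )
        return spec

    def validate(self, sample_info: pd.DataFrame) -> None:
        for name, levels in self.factors.items():
            observed = sample_info[name].astype(str)
            counts = observed.value_counts()
            for level in levels:
                if counts.get(level, 0) == 0:
                    raise ValueError(f"factor {name!r} level {level!r} has no samples")

    def condition_cells(self, sample_info: pd.DataFrame) -> np.ndarray:
        """Integer code of the factor-level combination of each sample
        (the 'condition' used when counting replicates)."""
        if not self.factors:
            return np.zeros(len(sample_info), dtype=int)
        key = sample_info[list(self.factors)].astype(str).agg("\x00".join, axis=1)
        return pd.factorize(key)[0]


@dataclass
class DesignMatrix:
    """A realized design matrix with column bookkeeping.

    ``columns`` are human-readable names; ``column_factor`` maps column
    index -> factor name for factor-indicator columns (None for the
    intercept, covariates and interactions); ``kind`` is "standard" or
    "expanded".
    """

    matrix: np.ndarray
    columns: list[str]
    column_factor: list[str | None]
    column_level: list[str | None]
    kind: str
    spec: DesignSpec

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_parameters(self) -> int:
        """Number of identifiable parameters (column rank)."""
        return int(np.linalg.matrix_rank(self.matrix))


def _factor_indicators(values: pd.Series, levels: list[str]) -> np.ndarray:
    vals = values.astype(str).to_numpy()
    return np.column_stack([(vals == lv).astype(float) for lv in levels])


def build_design(
    spec: DesignSpec, sample_info: pd.DataFrame, expanded: bool = False
) -> DesignMatrix:
    """Construct the design matrix for the given specification.

    When ``expanded`` is requested but interaction terms are present and
    all factors have exactly two levels, a standard matrix is returned
    instead (the single interaction coefficient is then the direct test
    of non-additivity).  Interactions involving factors with more than
    two levels are not supported.
    """
    spec.validate(sample_info)
    if spec.interactions:
        if all(len(lv) == 2 for lv in spec.factors.values()):
            expanded = False
        else:
            raise ValueError(
                "interaction terms are only supported when all factors have "
                "exactly two levels"
            )

    m = len(sample_info)
    cols: list[np.ndarray] = [np.ones(m)]
    names = ["Intercept"]
    col_factor: list[str | None] = [None]
    col_level: list[str | None] = [None]

    for name, levels in spec.factors.items():
        ind = _factor_indicators(sample_info[name], levels)
        if expanded:
            for k, lv in enumerate(levels):
                cols.append(ind[:, k])
                names.append(f"{name}_{lv}")
                col_factor.append(name)
                col_level.append(lv)
        else:
            for k, lv in enumerate(levels[1:], start=1):
                cols.append(ind[:, k])
                names.append(f"{name}_{lv}_vs_{levels[0]}")
                col_factor.append(name)
                col_level.append(lv)

    for name in spec.covariates:
        cols.append(sample_info[name].to_numpy(dtype=float))
        names.append(name)
        col_factor.append(None)
        col_level.append(None)

    for a, b in spec.interactions:
        ia = _factor_indicators(sample_info[a], spec.factors[a])[:, 1]
        ib = _factor_indicators(sample_info[b], spec.factors[b])[:, 1]
        cols.append(ia * ib)
        names.append(f"{a}:{b}")
        col_factor.append(None)
        col_level.append(None)

    X = np.column_stack(cols)
    return DesignMatrix(
        matrix=X,
        columns=names,
        column_factor=col_factor,
        column_level=col_level,
        kind="expanded" if expanded else "standard",
        spec=spec,
    )


def contrast_vector(
    design: DesignMatrix, factor: str, numerator: str, denominator: str
) -> np.ndarray:
    """Contrast vector for ``numerator`` vs ``denominator`` level of a
    factor, valid for both standard and expanded matrices."""
    if factor not in design.spec.factors:
        raise ValueError(f"unknown factor {factor!r}")
    levels = design.spec.factors[factor]
    for lv in (numerator, denominator):
        if lv not in levels:
            raise ValueError(f"unknown level {lv!r} of factor {factor!r}")
    c = np.zeros(design.n_columns)
    if design.kind == "expanded":
        for idx, (f, lv) in enumerate(zip(design.column_factor, design.column_level)):
            if f == factor and lv == numerator:
                c[idx] += 1.0
            if f == factor and lv == denominator:
                c[idx] -= 1.0
    else:
        base = levels[0]
        for idx, name in enumerate(design.columns):
            if name == f"{factor}_{numerator}_vs_{base}":
                c[idx] += 1.0
            if name == f"{factor}_{denominator}_vs_{base}":
                c[idx] -= 1.0
    return c
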