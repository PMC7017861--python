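"""Symbolic model structures, design matrices and parameter counting.

A model structure names one sub-model for each of the three components of the
dynamic three-state occupancy model:

* ``psi`` — the wet-next-year transition probabilities psi^m(t), indexed by the
  prior state m;
* ``R`` — the conditional breeding probabilities R^m(t) given wet in t+1;
* ``delta`` — the per-survey probability of detecting breeding evidence at a
  wet, occupied site (water detection is perfect, so delta is the only
  detection parameter).

Grammar (EBNF)::

    structure  = psi_part " " r_part " " delta_part
    psi_part   = "psi[" grouping "](" terms ")"
    r_part     = "R[" grouping "](" terms ")"
    delta_part = "delta(" terms ")"
    grouping   = "m" | "1=2" | "0=1" | "0,1=2"
    terms      = "." | term { "+" term }
    term       = "t" | covariate | covariate "*" covariate
    covariate  = name of a StudyData covariate token (veg, Vegave, depth,
                 Depthave, precip, Precipave, evap, Evapave, RO, ROave,
                 and *_lag1 copies); "×" is accepted as a product sign

The grouping partitions the prior state for psi/R: ``m`` keeps all three
states separate, ``1=2`` (equivalently ``0,1=2``) equates the two wet states,
``0=1`` equates the two unoccupied states.

Linear-predictor semantics (on the logit scale):

* a psi/R component with year term ``t`` gets one intercept per
  (state-group × interval) plus one slope per (state-group × covariate),
  slopes shared across years; without ``t`` it gets one intercept per
  state-group;
* the delta component with ``t`` gets one intercept per year plus one slope
  per covariate shared across years; without ``t``, a single intercept;
* two further coefficients are always present: the initial-year logit psi
  (probability wet in year 1) and logit R (breeding given wet in year 1).

Continuous covariates are standardized to zero mean / unit variance over the
records on which they enter the design; fitted probabilities, likelihood and
AICc are invariant to this affine choice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .data_io import StudyData, DataError

GROUPINGS = {
    "m": ((0,), (1,), (2,)),
    "1=2": ((0,), (1, 2)),
    "0,1=2": ((0,), (1, 2)),
    "0=1": ((0, 1), (2,)),
}

_KNOWN_BASE = {"veg", "Vegave", "depth", "Depthave",
               "precip", "Precipave", "evap", "Evapave", "RO", "ROave"}


class ParseError(ValueError):
    """Model string does not match the grammar."""


def _known_covariate(tok: str) -> bool:
    return tok in _KNOWN_BASE or (tok.endswith("_lag1") and tok[:-5] in _KNOWN_BASE)


@dataclass(frozen=True)
class ComponentSpec:
    component: str                      # "psi" | "R" | "delta"
    grouping: str = "m"                 # token; ignored for delta
    year_term: bool = False
    covariates: tuple = ()              # tokens, products as "a*b"

    @property
    def groups(self) -> tuple:
        if self.component == "delta":
            return ((0,),)
        return GROUPINGS[self.grouping]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def n_columns(self, n_years: int) -> int:
        """Number of coefficient columns this component contributes."""
        if self.component == "delta":
            n_int = n_years if self.year_term else 1
            return n_int + len(self.covariates)
        n_times = (n_years - 1) if self.year_term else 1
        return self.n_groups * n_times + self.n_groups * len(self.covariates)

    def canonical(self) -> str:
        terms = list(self.covariates) + (["t"] if self.year_term else [])
        inner = "+".join(terms) if terms else "."
        if self.component == "delta":
            return f"delta({inner})"
        return f"{self.component}[{self.grouping}]({inner})"


@dataclass(frozen=True)
class ModelStructure:
    psi: ComponentSpec
    r: ComponentSpec
    delta: ComponentSpec

    @property
    def name(self) -> str:
        return " ".join([self.psi.canonical(), self.r.canonical(),
                         self.delta.canonical()])

    def __str__(self) -> str:
        return self.name


_PART = re.compile(r"^(psi|R)\[([^\]]+)\]\(([^)]*)\)$")
_DELTA = re.compile(r"^delta\(([^)]*)\)$")


def _parse_terms(inner: str, where: str):
    inner = inner.replace("×", "*").strip()
    if inner in (".", ""):
        return False, ()
    year = False
    covs = []
    for term in inner.split("+"):
        term = term.strip()
        if term == "t":
            year = True
            continue
        factors = [f.strip() for f in term.split("*")]
        for f in factors:
            if not _known_covariate(f):
                pos = inner.find(f)
                raise ParseError(f"{where}: unknown covariate {f!r} at position {pos}")
        covs.append("*".join(factors))
    return year, tuple(covs)


def parse_component(text: str) -> ComponentSpec:
    """Parse a single component such as ``psi[m](Precipave+t)`` or ``delta(.)``."""
    text = text.strip()
    m = _DELTA.match(text)
    if m:
        year, covs = _parse_terms(m.group(1), text)
        return ComponentSpec("delta", "m", year, covs)
    m = _PART.match(text)
    if not m:
        raise ParseError(f"cannot parse component {text!r}")
    comp, grouping, inner = m.groups()
    grouping = grouping.strip()
    if grouping not in GROUPINGS:
        raise ParseError(f"{text}: unknown state grouping {grouping!r}")
    year, covs = _parse_terms(inner, text)
    return ComponentSpec(comp, grouping, year, covs)


def parse_model_structure(spec_string: str) -> ModelStructure:
    """Parse a canonical model string into a :class:`ModelStructure`.

    >>> parse_model_structure("psi[m](t) R[m](t) delta(Vegave+t)").name
    'psi[m](t) R[m](t) delta(Vegave+t)'
    """
    parts = re.findall(r"(?:psi|R)\[[^\]]*\]\([^)]*\)|delta\([^)]*\)",
                       spec_string.replace("×", "*"))
    if len(parts) != 3 or "".join(parts).replace(" ", "") != spec_string.replace("×", "*").replace(" ", ""):
        raise ParseError(f"expected 'psi[...](...) R[...](...) delta(...)', got {spec_string!r}")
    specs = {p.component: p for p in (parse_component(x) for x in parts)}
    if set(specs) != {"psi", "R", "delta"}:
        raise ParseError(f"structure must name psi, R and delta exactly once: {spec_string!r}")
    return ModelStructure(psi=specs["psi"], r=specs["R"], delta=specs["delta"])


def count_parameters(structure: ModelStructure, n_years: int) -> int:
    """Total identifiable parameter count K.

    K = 2 (initial logit psi, logit R) + columns of the psi component over the
    T−1 intervals + columns of the R component + columns of the delta
    component.
    """
    return (2 + structure.psi.n_columns(n_years)
            + structure.r.n_columns(n_years)
            + structure.delta.n_columns(n_years))


@dataclass
class DesignMatrices:
    """Per-component design tensors mapping coefficients to linear predictors.

    ``x_psi``/``x_r`` have shape (n_sites, T−1, 3, n_cols): rows are
    (site, interval, prior state) cells.  ``x_delta`` has shape
    (n_sites, T, n_cols).  ``beta`` is laid out as
    [logit psi1, logit R1, psi columns, R columns, delta columns].
    """

    structure: ModelStructure
    x_psi: np.ndarray
    x_r: np.ndarray
    x_delta: np.ndarray
    labels: list                      # coefficient labels, full beta order
    standardization: dict             # (component, token) -> (mean, sd)
    n_sites: int = 0
    n_years: int = 0

    @property
    def n_params(self) -> int:
        return 2 + self.x_psi.shape[-1] + self.x_r.shape[-1] + self.x_delta.shape[-1]

    def split(self, beta: np.ndarray):
        """Split a full coefficient vector into its component blocks."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape[-1] != self.n_params:
            raise ValueError(f"expected {self.n_params} coefficients, got {beta.shape[-1]}")
        c1 = 2 + self.x_psi.shape[-1]
        c2 = c1 + self.x_r.shape[-1]
        return beta[:2], beta[2:c1], beta[c1:c2], beta[c2:]

    def standardize_value(self, component: str, token: str, raw):
        mean, sd = self.standardization[(component, token)]
        return (np.asarray(raw, dtype=float) - mean) / sd


def _covariate_values(data: StudyData, token: str) -> np.ndarray:
    """Raw (n_sites, T) values for a term token, products multiplied out later."""
    return np.asarray(data.covariate(token), dtype=float)


def _component_design(spec: ComponentSpec, data: StudyData, standardization: dict):
    """Design tensor and labels for one component.

    psi/R rows are transitions into year t+1 (interval t); time-varying
    covariates take their value in the target year t+1, so a ``*_lag1``
    covariate contributes the year-t value.  delta rows are survey years.
    """
    n, T = data.n_sites, data.n_years
    is_delta = spec.component == "delta"
    if is_delta:
        n_time, n_states = T, 1
        year_idx = np.arange(T)
    else:
        n_time, n_states = T - 1, 3
        year_idx = np.arange(1, T)      # covariate timing: target year

    cols, labels = [], []
    # intercepts
    if is_delta:
        if spec.year_term:
            for t in range(T):
                col = np.zeros((n, n_time, n_states))
                col[:, t, :] = 1.0
                cols.append(col)
                labels.append(f"delta:int[year{t + 1}]")
        else:
            cols.append(np.ones((n, n_time, n_states)))
            labels.append("delta:int")
    else:
        for g, group in enumerate(spec.groups):
            gname = "".join(str(s) for s in group)
            if spec.year_term:
                for t in range(n_time):
                    col = np.zeros((n, n_time, n_states))
                    for s in group:
                        col[:, t, s] = 1.0
                    cols.append(col)
                    labels.append(f"{spec.component}:int[m{gname},i{t + 1}]")
            else:
                col = np.zeros((n, n_time, n_states))
                for s in group:
                    col[:, :, s] = 1.0
                cols.append(col)
                labels.append(f"{spec.component}:int[m{gname}]")

    # covariate slopes
    def standardized(token):
        factors = token.split("*")
        vals = np.ones((n, T))
        for f in factors:
            raw = _covariate_values(data, f)
            key = (spec.component, f)
            if key not in standardization:
                sel = raw[:, year_idx]
                finite = sel[np.isfinite(sel)]
                if finite.size == 0:
                    raise DataError(f"covariate {f!r} has no finite values "
                                    f"for component {spec.component}")
                sd = float(np.std(finite))
                standardization[key] = (float(np.mean(finite)), sd if sd > 0 else 1.0)
            mean, sd = standardization[key]
            vals = vals * ((raw - mean) / sd)
        sel = vals[:, year_idx]
        if not np.all(np.isfinite(sel)):
            raise DataError(f"covariate term {token!r} has missing values on "
                            f"records entering the {spec.component} design")
        return sel                                  # (n, n_time)

    for token in spec.covariates:
        z = standardized(token)
        if is_delta:
            cols.append(z[:, :, None])
            labels.append(f"delta:{token}")
        else:
            for group in spec.groups:
                gname = "".join(str(s) for s in group)
                col = np.zeros((n, n_time, n_states))
                for s in group:
                    col[:, :, s] = z
                cols.append(col)
                labels.append(f"{spec.component}:{token}[m{gname}]")

    x = np.stack(cols, axis=-1) if cols else np.zeros((n, n_time, n_states, 0))
    if is_delta:
        x = x[:, :, 0, :]                           # (n, T, c)
    return x, labels


def build_design_matrices(structure: ModelStructure, data: StudyData) -> DesignMatrices:
    """Build the per-component design tensors for ``structure`` on ``data``."""
    standardization: dict = {}
    x_psi, l_psi = _component_design(structure.psi, data, standardization)
    x_r, l_r = _component_design(structure.r, data, standardization)
    x_delta, l_delta = _component_design(structure.delta, data, standardization)
    labels = ["init:logit_psi", "init:logit_R"] + l_psi + l_r + l_delta
    dm = DesignMatrices(structure=structure, x_psi=x_psi, x_r=x_r,
                        x_delta=x_delta, labels=labels,
                        standardization=standardization,
                        n_sites=data.n_sites, n_years=data.n_years)
    expected = count_parameters(structure, data.n_years)
    assert dm.n_params == expected, (dm.n_params, expected)
    return dm
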