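"""Selection–mutation–translation model of synonymous codon use.

Within each synonymous family the probability of a codon is proportional to
the product of up to three biases:

* selection on nitrogen content, α(C) = exp(2N_g·s · N_mRNA(C)), with the
  composite parameter ``sel_n`` = 2N_g·s (negative values favour
  nitrogen-poor codons);
* mutation bias toward AT, β(C) = δ^AT (1−δ)^GC with δ = m/(m+1) and
  ``mut_m`` = m the equilibrium AT:GC odds;
* translational selection, η(C) = exp(2N_g·σ · ω(C)), with ``sel_tai`` =
  2N_g·σ acting on the tRNA adaptiveness ω.

The likelihood of a set of coding sequences is ℒ = Π_C p(C|θ)^{N_C} over
pooled sense-codon counts; fitting is a deterministic brute-force grid
search with one zoom pass, with grid ties broken toward the neutral
parameter point (sel_n = 0, m = 1, sel_tai = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .counting import CodonCounts, CodonProbTable
from .errors import DegenerateDataError, MissingTaiError, NitrocodonError
from .nitrogen import GeneticCode, STANDARD_CODE, nitrogen_mrna, normalize_codon
from .tai import TaiTable

#: Model variants and their free parameters.
VARIANTS: dict[str, tuple[str, ...]] = {
    "mutation_only": ("mut_m",),
    "selection_only": ("sel_n",),
    "tai_only": ("sel_tai",),
    "selection_mutation": ("sel_n", "mut_m"),
    "mutation_tai": ("mut_m", "sel_tai"),
    "selection_mutation_tai": ("sel_n", "mut_m", "sel_tai"),
}

_VARIANT_ALIASES = {
    "selection+mutation": "selection_mutation",
    "mutation+tai": "mutation_tai",
    "selection+mutation+tai": "selection_mutation_tai",
}


def canonical_variant(variant: str) -> str:
    v = _VARIANT_ALIASES.get(variant, variant)
    if v not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; one of {sorted(VARIANTS)}")
    return v


@dataclass(frozen=True)
class ModelParams:
    """Parameter point of one model variant.

    Parameters absent from the variant are held at their neutral values
    (sel_n = 0, mut_m = 1, sel_tai = 0).
    """

    variant: str = "selection_mutation"
    sel_n: float = 0.0
    mut_m: float = 1.0
    sel_tai: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "variant", canonical_variant(self.variant))
        if self.mut_m <= 0:
            raise NitrocodonError(f"mutation bias m must be > 0, got {self.mut_m}")
        free = VARIANTS[self.variant]
        if "sel_n" not in free and self.sel_n != 0.0:
            raise NitrocodonError(f"sel_n must stay neutral (0) under variant {self.variant}")
        if "mut_m" not in free and self.mut_m != 1.0:
            raise NitrocodonError(f"mut_m must stay neutral (1) under variant {self.variant}")
        if "sel_tai" not in free and self.sel_tai != 0.0:
            raise NitrocodonError(f"sel_tai must stay neutral (0) under variant {self.variant}")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return VARIANTS[self.variant]

    @property
    def k(self) -> int:
        return len(self.free_parameters)

    @property
    def uses_tai(self) -> bool:
        return "sel_tai" in self.free_parameters


def selection_bias(codon: str, sel_n: float) -> float:
    """α(C) = exp(sel_n · N_mRNA(C)); selection bias toward *codon*."""
    return math.exp(sel_n * nitrogen_mrna(codon))


def mutation_delta(mut_m: float) -> float:
    """δ = m/(m+1): equilibrium probability that a site is A or T."""
    if mut_m <= 0:
        raise NitrocodonError(f"mutation bias m must be > 0, got {mut_m}")
    return mut_m / (mut_m + 1.0)


def mutation_bias(codon: str, mut_m: float) -> float:
    """β(C) = δ^AT · (1−δ)^GC with AT/GC the codon's base counts."""
    c = normalize_codon(codon)
    delta = mutation_delta(mut_m)
    at = sum(1 for b in c if b in "AT")
    return delta**at * (1.0 - delta) ** (3 - at)


def _nitrogen_vector(code: GeneticCode, nitrogen_values) -> np.ndarray:
    if nitrogen_values is None:
        return np.array([nitrogen_mrna(c) for c in code.sense_codons], dtype=float)
    if isinstance(nitrogen_values, Mapping):
        return np.array([float(nitrogen_values[c]) for c in code.sense_codons])
    arr = np.asarray(nitrogen_values, dtype=float)
    if arr.shape != (len(code.sense_codons),):
        raise NitrocodonError(
            f"nitrogen_values must map every sense codon; got shape {arr.shape}"
        )
    return arr


def _omega_vector(code: GeneticCode, tai: TaiTable | None, needed: bool) -> np.ndarray:
    if not needed:
        return np.zeros(len(code.sense_codons))
    if tai is None:
        raise MissingTaiError("this model variant includes translational selection; pass a TaiTable")
    return np.array([float(tai.omega[c]) for c in code.sense_codons])


def _family_index(code: GeneticCode) -> tuple[np.ndarray, int]:
    aas = sorted(code.families)
    fam_of = {aa: i for i, aa in enumerate(aas)}
    idx = np.array([fam_of[code.codon_to_aa[c]] for c in code.sense_codons])
    return idx, len(aas)


def codon_probs(
    params: ModelParams,
    code: GeneticCode = STANDARD_CODE,
    tai: TaiTable | None = None,
    nitrogen_values=None,
) -> CodonProbTable:
    """Model codon-use probabilities, normalised within each synonymous family.

    ``nitrogen_values`` optionally overrides the per-codon nitrogen content
    (used by the permutation test, which shuffles the values over codons).
    """
    nvec = _nitrogen_vector(code, nitrogen_values)
    omega = _omega_vector(code, tai, params.uses_tai)
    at = np.array([sum(1 for b in c if b in "AT") for c in code.sense_codons], dtype=float)
    delta = mutation_delta(params.mut_m)
    logw = (
        params.sel_n * nvec
        + at * math.log(delta)
        + (3.0 - at) * math.log(1.0 - delta)
        + params.sel_tai * omega
    )
    w = np.exp(logw)
    famidx, nfam = _family_index(code)
    famsum = np.bincount(famidx, weights=w, minlength=nfam)
    probs = w / famsum[famidx]
    return CodonProbTable(probs=dict(zip(code.sense_codons, probs)), code=code)


def _counts_vector(counts, code: GeneticCode) -> np.ndarray:
    pooled = counts.pooled if isinstance(counts, CodonCounts) else dict(counts)
    unknown = set(pooled) - set(code.sense_codons)
    if unknown:
        raise NitrocodonError(f"counts contain non-sense codons for table {code.table_id}: {sorted(unknown)}")
    return np.array([float(pooled.get(c, 0)) for c in code.sense_codons])


def log_likelihood(
    params: ModelParams,
    counts,
    code: GeneticCode = STANDARD_CODE,
    tai: TaiTable | None = None,
    nitrogen_values=None,
) -> float:
    """Σ_C N_C · ln p(C|θ) over pooled sense-codon counts.

    Single-codon families contribute 0; a codon with positive count but zero
    model probability yields −inf with a warning.
    """
    cvec = _counts_vector(counts, code)
    table = codon_probs(params, code=code, tai=tai, nitrogen_values=nitrogen_values)
    pvec = np.array([table.probs[c] for c in code.sense_codons])
    bad = (cvec > 0) & (pvec == 0.0)
    if bad.any():
        warnings.warn("observed codons with zero model probability; log-likelihood is -inf")
        return float("-inf")
    mask = cvec > 0
    return float(np.sum(cvec[mask] * np.log(pvec[mask])))


@dataclass(frozen=True)
class GridSpec:
    """Brute-force search specification.

    ``sel_n`` and ``sel_tai`` are linear (lo, hi, step) grids; ``mut_m`` is
    log-spaced over ``m_range`` with ``m_points`` points (201 by default so
    the neutral point m = 1 sits exactly on the symmetric grid).  One zoom
    pass refines the grid ``zoom``-fold around the coarse optimum.  ``fixed``
    pins a parameter to a single value (e.g. per-gene fits with genome-wide m).
    """

    sel_n: tuple[float, float, float] = (-1.0, 1.0, 0.01)
    m_range: tuple[float, float] = (0.05, 20.0)
    m_points: int = 201
    sel_tai: tuple[float, float, float] = (-1.0, 1.0, 0.01)
    zoom: int = 10
    zoom_halfwidth: int = 1  # coarse steps either side of the optimum
    fixed: Mapping[str, float] = field(default_factory=dict)

    def linear_axis(self, name: str) -> np.ndarray:
        lo, hi, step = getattr(self, name)
        n = int(round((hi - lo) / step)) + 1
        return np.linspace(lo, hi, n)

    def m_axis(self) -> np.ndarray:
        lo, hi = self.m_range
        return np.exp(np.linspace(math.log(lo), math.log(hi), self.m_points))


#: Coarser default grid for permutation-test refits (resolution choice only;
#: observed and permuted data are fitted on the same grid).
PERMUTATION_GRID = GridSpec(sel_n=(-1.0, 1.0, 0.02), m_points=81, sel_tai=(-1.0, 1.0, 0.02))


@dataclass
class FitResult:
    """Maximum-likelihood fit: parameters, log-likelihood, AIC and the
    implied codon-probability table, plus metadata describing the search."""

    params: ModelParams
    loglik: float
    aic: float
    probs: CodonProbTable
    grid_meta: dict

    def to_dict(self) -> dict:
        return {
            "variant": self.params.variant,
            "sel_n": self.params.sel_n,
            "mut_m": self.params.mut_m,
            "sel_tai": self.params.sel_tai,
            "loglik": self.loglik,
            "aic": self.aic,
            "grid_meta": self.grid_meta,
        }


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2k − 2·lnℒ, k = free-parameter count."""
    return 2.0 * fit.params.k - 2.0 * fit.loglik


def _grid_loglik(
    cvec, famidx, nfam, nvec, at, omega, sel_axis, m_axis, tai_axis
) -> np.ndarray:
    """Log-likelihood over the cartesian grid, shape (n_sel, n_m, n_tai)."""
    gc = 3.0 - at
    famtot = np.bincount(famidx, weights=cvec, minlength=nfam)
    fmat = np.zeros((len(famidx), nfam))
    fmat[np.arange(len(famidx)), famidx] = 1.0

    S = sel_axis[:, None] * nvec[None, :]                      # (ns, C)
    delta = m_axis / (m_axis + 1.0)
    B = at[None, :] * np.log(delta)[:, None] + gc[None, :] * np.log1p(-delta)[:, None]
    T = tai_axis[:, None] * omega[None, :]                     # (nt, C)

    s_dot = S @ cvec
    b_dot = B @ cvec
    t_dot = T @ cvec
    ES, EB, ET = np.exp(S), np.exp(B), np.exp(T)

    ns, nm, nt = len(sel_axis), len(m_axis), len(tai_axis)
    out = np.empty((ns, nm, nt))
    for k in range(nt):
        w = ES[:, None, :] * (EB[None, :, :] * ET[k][None, None, :])
        famsum = w.reshape(-1, len(famidx)) @ fmat
        penalty = (np.log(famsum) @ famtot).reshape(ns, nm)
        out[:, :, k] = s_dot[:, None] + b_dot[None, :] + t_dot[k] - penalty
    return out


def _pick(loglik: np.ndarray, sel_axis, m_axis, tai_axis) -> tuple[int, int, int]:
    """Argmax with ties broken toward the neutral parameter point."""
    best = loglik.max()
    tied = np.argwhere(loglik >= best - 1e-10)
    keys = [
        (abs(sel_axis[i]), abs(math.log(m_axis[j])), abs(tai_axis[k]), i, j, k)
        for i, j, k in tied
    ]
    _, _, _, i, j, k = min(keys)
    return i, j, k


def fit(
    counts,
    variant: str = "selection_mutation",
    code: GeneticCode = STANDARD_CODE,
    grid: GridSpec | None = None,
    tai: TaiTable | None = None,
    nitrogen_values=None,
) -> FitResult:
    """Brute-force maximum-likelihood fit of one model variant.

    A coarse pass over the full grid is refined by one zoom pass at
    ``grid.zoom``-times the resolution around the coarse optimum (clipped to
    the original bounds).  Deterministic for fixed inputs.
    """
    variant = canonical_variant(variant)
    grid = grid or GridSpec()
    free = VARIANTS[variant]
    cvec = _counts_vector(counts, code)
    famidx, nfam = _family_index(code)
    famtot = np.bincount(famidx, weights=cvec, minlength=nfam)
    fam_sizes = np.bincount(famidx, minlength=nfam)
    if not np.any((fam_sizes > 1) & (famtot > 0)):
        raise DegenerateDataError(
            "no multi-codon family has observations; the model parameters are unidentifiable"
        )
    nvec = _nitrogen_vector(code, nitrogen_values)
    omega = _omega_vector(code, tai, "sel_tai" in free)
    at = np.array([sum(1 for b in c if b in "AT") for c in code.sense_codons], dtype=float)

    def axis_for(name: str) -> np.ndarray:
        if name in grid.fixed:
            return np.array([float(grid.fixed[name])])
        if name not in free:
            return np.array([1.0 if name == "mut_m" else 0.0])
        return grid.m_axis() if name == "mut_m" else grid.linear_axis(name)

    sel_axis, m_axis, tai_axis = (axis_for(n) for n in ("sel_n", "mut_m", "sel_tai"))
    ll = _grid_loglik(cvec, famidx, nfam, nvec, at, omega, sel_axis, m_axis, tai_axis)
    i, j, k = _pick(ll, sel_axis, m_axis, tai_axis)

    def refined_linear(axis: np.ndarray, idx: int, spec_name: str) -> np.ndarray:
        if len(axis) == 1:
            return axis
        lo, hi, step = getattr(grid, spec_name)
        centre = axis[idx]
        half = grid.zoom_halfwidth * step
        n = 2 * grid.zoom_halfwidth * grid.zoom + 1
        return np.clip(np.linspace(centre - half, centre + half, n), lo, hi)

    def refined_m(axis: np.ndarray, idx: int) -> np.ndarray:
        if len(axis) == 1:
            return axis
        log_lo, log_hi = math.log(grid.m_range[0]), math.log(grid.m_range[1])
        log_step = (log_hi - log_lo) / (grid.m_points - 1)
        centre = math.log(axis[idx])
        half = grid.zoom_halfwidth * log_step
        n = 2 * grid.zoom_halfwidth * grid.zoom + 1
        return np.exp(np.clip(np.linspace(centre - half, centre + half, n), log_lo, log_hi))

    sel_fine = refined_linear(sel_axis, i, "sel_n")
    m_fine = refined_m(m_axis, j)
    tai_fine = refined_linear(tai_axis, k, "sel_tai")
    ll2 = _grid_loglik(cvec, famidx, nfam, nvec, at, omega, sel_fine, m_fine, tai_fine)
    i2, j2, k2 = _pick(ll2, sel_fine, m_fine, tai_fine)

    params = ModelParams(
        variant=variant,
        sel_n=float(sel_fine[i2]),
        mut_m=float(m_fine[j2]),
        sel_tai=float(tai_fine[k2]),
    )
    best_ll = float(ll2[i2, j2, k2])
    probs = codon_probs(params, code=code, tai=tai, nitrogen_values=nitrogen_values)
    meta = {
        "variant": variant,
        "free_parameters": list(free),
        "fixed": dict(grid.fixed),
        "coarse_shape": list(ll.shape),
        "zoom": grid.zoom,
        "refined_steps": {
            "sel_n": grid.sel_n[2] / grid.zoom,
            "log_m": (math.log(grid.m_range[1]) - math.log(grid.m_range[0]))
            / (grid.m_points - 1)
            / grid.zoom,
            "sel_tai": grid.sel_tai[2] / grid.zoom,
        },
    }
    return FitResult(
        params=params,
        loglik=best_ll,
        aic=2.0 * params.k - 2.0 * best_ll,
        probs=probs,
        grid_meta=meta,
    )


def fit_per_species(
    counts_by_species: Mapping[str, CodonCounts],
    variant: str = "selection_mutation",
    code: GeneticCode = STANDARD_CODE,
    grid: GridSpec | None = None,
    tai: TaiTable | None = None,
) -> dict[str, FitResult]:
    """Independent fits per species (the group-level alternative pools counts)."""
    return {
        sp: fit(c, variant=variant, code=code, grid=grid, tai=tai)
        for sp, c in counts_by_species.items()
    }


def pool_counts(counts_by_species: Mapping[str, CodonCounts], label: str = "pooled") -> CodonCounts:
    """Pool codon counts across species for a group-level fit."""
    pooled: dict[str, float] = {}
    for c in counts_by_species.values():
        for codon, n in c.pooled.items():
            pooled[codon] = pooled.get(codon, 0) + n
    return CodonCounts.from_pooled(pooled, species_id=label)
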