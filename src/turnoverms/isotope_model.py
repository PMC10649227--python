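"""Mass-isotopomer pattern computations for heavy-water labeling.

During ²H₂O metabolic labeling, deuterium enters newly synthesised
amino acids and remodels a peptide's mass-isotopomer distribution.
This module computes:

* the natural (unlabeled) isotope pattern of a peptide from its
  elemental composition, by iterated convolution of per-element
  isotope distributions;
* the fully labeled pattern, modeled as the natural pattern convolved
  with a Binomial(NEH, pX) distribution over the NEH metabolically
  exchangeable hydrogens, where pX = (pW - pH)/(1 - pH) is the excess
  deuterium fraction at body-water enrichment pW;
* the monoisotopic relative isotope abundance (RIA) from either the
  complete six-peak profile, I0 = A0 / sum(A0..A5), or from the ratio
  of a single pair of undistorted mass isotopomers (the partial-profile
  estimator, robust to co-eluting contaminants that corrupt some
  channels);
* the plateau RIA reached at full labeling,
  I0_asymp = I0(0) * (1 - pW/(1 - pH))**NEH.

Patterns are plain 1-D numpy arrays; index 0 is the monoisotope.
Internally patterns carry ``INTERNAL_PEAKS`` (10) isotopomers to keep
truncation error negligible, while RIAs are always defined over the
first ``PROFILE_PEAKS`` (6) peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .constants import (
    ELEMENT_ISOTOPES,
    EXCHANGEABLE_HYDROGENS,
    NATURAL_DEUTERIUM,
    PEPTIDE_TERMINI,
    PROTON_MASS,
    RESIDUE_COMPOSITION,
)

#: Number of mass isotopomers over which RIAs are defined (M0..M5).
PROFILE_PEAKS = 6
#: Number of isotopomers carried internally to limit truncation error.
INTERNAL_PEAKS = 10

__all__ = [
    "PROFILE_PEAKS",
    "INTERNAL_PEAKS",
    "PeptideSpec",
    "EnrichmentModel",
    "peptide_composition",
    "peptide_mz",
    "count_exchangeable_hydrogens",
    "natural_isotope_pattern",
    "ria_from_complete_profile",
    "asymptotic_ria",
    "labeled_pattern",
    "mixture_pattern",
    "ria_from_isotopomer_ratio",
    "isotope_deviation",
]


def peptide_composition(sequence: str) -> dict[str, int]:
    """Elemental composition of an unmodified linear peptide."""
    comp = dict(PEPTIDE_TERMINI)
    for aa in sequence:
        try:
            residue = RESIDUE_COMPOSITION[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue: {aa!r}") from None
        for elem, n in residue.items():
            comp[elem] = comp.get(elem, 0) + n
    return comp


def count_exchangeable_hydrogens(
    sequence: str, table: dict[str, float] | None = None
) -> float:
    """Number of metabolically exchangeable hydrogens (NEH) of a peptide.

    Sums per-residue accessible-hydrogen values.  The packaged table
    holds the Commerford-style averages used in the heavy-water
    turnover literature; pass ``table`` to override.
    """
    table = EXCHANGEABLE_HYDROGENS if table is None else table
    total = 0.0
    for aa in sequence:
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue: {aa!r}") from None
    return total


def peptide_mz(sequence: str, charge: int) -> float:
    """Monoisotopic m/z of an unmodified peptide at the given charge."""
    comp = peptide_composition(sequence)
    mass = sum(ELEMENT_ISOTOPES[e][0][0] * n for e, n in comp.items())
    return (mass + charge * PROTON_MASS) / charge


@dataclass
class PeptideSpec:
    """Identity and composition of one peptide/charge species."""

    sequence: str
    charge: int
    mz: float = 0.0
    neh: float = -1.0
    composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if not self.composition:
            self.composition = peptide_composition(self.sequence)
        if self.neh < 0:
            self.neh = count_exchangeable_hydrogens(self.sequence)
        if self.neh > self.composition.get("H", 0):
            raise ValueError("NEH exceeds the peptide's hydrogen count")
        if self.mz <= 0:
            self.mz = peptide_mz(self.sequence, self.charge)


@dataclass(frozen=True)
class EnrichmentModel:
    """Body-water deuterium enrichment during labeling.

    pW is the body-water deuterium fraction during the experiment; pH
    is the natural deuterium abundance.  pW = 0 models an unlabeled
    sample.
    """

    pW: float
    pH: float = NATURAL_DEUTERIUM

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH < 1.0):
            raise ValueError("pH must lie in [0, 1)")
        if not (0.0 <= self.pW < 1.0):
            raise ValueError("pW must lie in [0, 1)")
        if self.pW != 0.0 and self.pW <= self.pH:
            raise ValueError("labeling requires pW > pH")

    @property
    def excess_fraction(self) -> float:
        """Excess deuterium fraction pX = (pW - pH)/(1 - pH), 0 if unlabeled."""
        if self.pW == 0.0:
            return 0.0
        return (self.pW - self.pH) / (1.0 - self.pH)


def _as_pattern(x, name: str = "pattern") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} must be a 1-D array of length >= 2")
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative abundances")
    return arr


def normalize(pattern) -> np.ndarray:
    """Scale abundances to sum to 1."""
    arr = _as_pattern(pattern)
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero pattern")
    return arr / total


def natural_isotope_pattern(
    spec: PeptideSpec | dict[str, int], L: int = INTERNAL_PEAKS
) -> np.ndarray:
    """Natural isotope pattern of a molecule, first ``L`` isotopomers.

    Iterated convolution of per-element isotope distributions
    (abundances aggregated at nominal mass offsets), truncated to
    ``L`` peaks and renormalized.
    """
    comp = spec.composition if isinstance(spec, PeptideSpec) else spec
    if not comp:
        raise ValueError("empty elemental composition")
    if L < 2:
        raise ValueError("need at least two isotopomer peaks")
    pattern = np.zeros(L)
    pattern[0] = 1.0
    for elem, count in comp.items():
        try:
            isotopes = ELEMENT_ISOTOPES[elem]
        except KeyError:
            raise ValueError(f"unknown element symbol: {elem!r}") from None
        base = np.zeros(L)
        for iso_mass, iso_ab in isotopes:
            offset = int(round(iso_mass - isotopes[0][0]))
            if offset < L:
                base[offset] += iso_ab
        # exponentiation by squaring of the truncated convolution power
        n = count
        power = base
        while n:
            if n & 1:
                pattern = np.convolve(pattern, power)[:L]
            n >>= 1
            if n:
                power = np.convolve(power, power)[:L]
    return pattern / pattern.sum()


def ria_from_complete_profile(raw) -> float:
    """Monoisotopic RIA from the complete six-peak profile.

    I0 = A0 / sum_{i=0..5} Ai, computed from raw (unnormalized)
    isotopomer abundances.
    """
    arr = _as_pattern(raw, "profile")
    if arr.size < PROFILE_PEAKS:
        raise ValueError(f"profile needs >= {PROFILE_PEAKS} isotopomers")
    window = arr[:PROFILE_PEAKS]
    total = window.sum()
    if total <= 0:
        raise ValueError("undefined RIA: all-zero six-peak profile")
    return float(window[0] / total)


def asymptotic_ria(
    I0_natural: float, model: EnrichmentModel, neh: float
) -> float:
    """Plateau monoisotopic RIA at full labeling.

    I0_asymp = I0(0) * (1 - pW/(1 - pH))**NEH.  Each of the NEH
    exchangeable hydrogens independently avoids deuterium with
    probability 1 - pX, so the monoisotope survives with that
    probability to the NEH-th power.
    """
    if not (0.0 < I0_natural <= 1.0):
        raise ValueError("I0_natural must lie in (0, 1]")
    if neh < 0:
        raise ValueError("NEH must be nonnegative")
    if model.pW >= 1.0 - model.pH:
        raise ValueError("invalid enrichment: pW >= 1 - pH")
    return I0_natural * (1.0 - model.pW / (1.0 - model.pH)) ** neh


def _binomial_weights(n: float, pX: float, L: int) -> np.ndarray:
    """Label-count distribution over NEH exchangeable hydrogens.

    Integer NEH gives the plain Binomial(NEH, pX) pmf.  The packaged
    per-residue NEH table holds empirical averages, so NEH is usually
    fractional; then the two adjacent integer binomials are mixed with
    the weight chosen so the zero-label term equals (1 - pX)**NEH
    exactly — the monoisotope survival probability the plateau formula
    assumes.
    """
    n0 = int(math.floor(n))
    k = np.arange(L)
    w0 = binom.pmf(k, n0, pX)
    if n == n0:
        return w0
    w1 = binom.pmf(k, n0 + 1, pX)
    # solve (1-w)*(1-pX)^n0 + w*(1-pX)^(n0+1) = (1-pX)^n for w
    w = (1.0 - (1.0 - pX) ** (n - n0)) / pX
    return (1.0 - w) * w0 + w * w1


def labeled_pattern(natural, neh: float, pX: float) -> np.ndarray:
    """Isotope pattern of the fully labeled peptide.

    Convolution of the natural pattern with the label-count
    distribution over the NEH exchangeable hydrogens (binomial at
    success probability pX), truncated to the input length and
    renormalized.
    """
    nat = normalize(natural)
    if not (0.0 <= pX < 1.0):
        raise ValueError("pX must lie in [0, 1)")
    if neh < 0:
        raise ValueError("NEH must be nonnegative")
    if pX < 1e-12 or neh == 0:
        return nat.copy()
    L = nat.size
    weights = _binomial_weights(neh, pX, L)
    out = np.convolve(nat, weights)[:L]
    return out / out.sum()


def mixture_pattern(natural, labeled, f: float) -> np.ndarray:
    """Composite profile of unlabeled and labeled peptide populations.

    (1 - f) * natural + f * labeled, renormalized; f is the labeled
    (newly synthesised) fraction.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("mixture fraction f must lie in [0, 1]")
    nat = normalize(natural)
    lab = normalize(labeled)
    if nat.size != lab.size:
        raise ValueError("patterns must have equal length")
    mix = (1.0 - f) * nat + f * lab
    return mix / mix.sum()


def _six_norm(pattern: np.ndarray) -> np.ndarray:
    window = np.asarray(pattern, dtype=float)[:PROFILE_PEAKS]
    return window / window.sum()


def ria_from_isotopomer_ratio(
    ratio: float, i: int, j: int, natural, labeled
) -> float:
    """Monoisotopic RIA from the ratio of one pair of mass isotopomers.

    Given the observed abundance ratio A_i/A_j of two undistorted
    channels, inverts the mixture model: finds the labeled fraction f
    in [0, 1] at which the model ratio of the natural/labeled mixture
    equals the observation (bracketed root finding, tolerance 1e-10),
    then returns the equivalent complete-profile monoisotopic RIA
    I0 = (1 - f) * natural[0] + f * labeled[0] with both terms from
    six-peak-normalized patterns, so the result coincides with the
    complete-profile RIA on undistorted data.

    Raises ``ValueError`` when the observed ratio falls outside the
    model's attainable range (a sign of interference on the chosen
    pair) or when the model ratio is not strictly monotone in f
    (unsupported pair).
    """
    if i == j:
        raise ValueError("isotopomer indices must differ")
    if not (0 <= i < PROFILE_PEAKS and 0 <= j < PROFILE_PEAKS):
        raise ValueError(f"indices must be < {PROFILE_PEAKS}")
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError("ratio must be a positive finite number")
    nat6 = _six_norm(normalize(natural))
    lab6 = _six_norm(normalize(labeled))

    def model_ratio(f: float) -> float:
        num = (1.0 - f) * nat6[i] + f * lab6[i]
        den = (1.0 - f) * nat6[j] + f * lab6[j]
        if den <= 0:
            return np.inf
        return num / den

    grid = np.linspace(0.0, 1.0, 201)
    values = np.array([model_ratio(f) for f in grid])
    diffs = np.diff(values)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(
            f"model ratio A{i}/A{j} is not strictly monotone in the "
            "labeled fraction; unsupported isotopomer pair"
        )
    lo, hi = (values[0], values[-1]) if values[0] < values[-1] else (values[-1], values[0])
    if not (lo - 1e-12 <= ratio <= hi + 1e-12):
        raise ValueError(
            f"observed ratio {ratio:.6g} outside the attainable range "
            f"[{lo:.6g}, {hi:.6g}] of pair ({i},{j}); likely interference"
        )
    ratio = min(max(ratio, lo), hi)
    if np.isclose(model_ratio(0.0), ratio, rtol=0, atol=1e-14):
        f_hat = 0.0
    elif np.isclose(model_ratio(1.0), ratio, rtol=0, atol=1e-14):
        f_hat = 1.0
    else:
        f_hat = brentq(lambda f: model_ratio(f) - ratio, 0.0, 1.0, xtol=1e-10)
    return float((1.0 - f_hat) * nat6[0] + f_hat * lab6[0])


def isotope_deviation(observed, theoretical) -> float:
    """Absolute deviation between two six-peak-normalized profiles.

    Sum over i=0..5 of |observed_i - theoretical_i|; 0 for identical
    profiles, at most 2.  Used as a spectral-quality filter on the
    unlabeled peptide.
    """
    obs = _six_norm(normalize(observed))
    theo = _six_norm(normalize(theoretical))
    return float(np.abs(obs - theo).sum())
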