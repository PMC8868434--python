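"""Synthetic fatty-acid profiles and dose-response series with known ground
truth, plus the packaged reference diatom profiles.

Compositions are drawn from a Dirichlet distribution over a configurable
species list (so they sum to exactly 100 before not-detected zeroing);
dose-response series come from a four-parameter logistic with optional
additive Gaussian noise.  Every generator takes an explicit seed — there is
no global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .bioassay import AbsorbanceTriple, DoseResponse, four_param_logistic
from .nomenclature import parse_shorthand
from .profile import FattyAcidProfile, ProfileEntry, read_profile_csv

__all__ = [
    "ProfileSimSpec",
    "DoseSimSpec",
    "simulate_profile",
    "simulate_dose_response",
    "dose_response_to_plate",
    "reference_profiles",
    "REFERENCE_SPECIES",
]

#: Shorthand codes of the packaged reference profiles: ~20 detected species
#: across all three saturation classes, one explicitly-trans isomer, and
#: both EPA and DHA.  Default species list for profile simulation.
REFERENCE_SPECIES = (
    "C6:0", "C10:0", "C12:0", "C14:0", "C15:0", "C16:0", "C17:0", "C18:0",
    "C22:0", "C24:0",
    "C14:1", "C16:1", "C17:1", "C18:1n9t", "C18:1n9c", "C22:1n9", "C24:1n9",
    "C18:3n6", "C18:2n6c", "C20:4n6", "C20:5n3", "C20:3n6", "C20:2n6",
    "C22:6n3",
)

_REFERENCE_FILES = {
    "Ano": ("anomoeoneis_d039.csv", 9.92),
    "Rho": ("rhopalodia_d020.csv", 12.72),
}


@dataclass(frozen=True)
class ProfileSimSpec:
    """Recipe for one random compositional profile.

    ``concentration_vector`` gives the Dirichlet weights, one per species
    (all positive); ``nd_probability`` independently zeroes each species to
    mimic not-detected entries.
    """

    seed: int
    species_list: tuple[str, ...] = REFERENCE_SPECIES
    concentration_vector: Optional[tuple[float, ...]] = None
    nd_probability: float = 0.0

    def __post_init__(self) -> None:
        if not self.species_list:
            raise ValueError("species list must not be empty")
        if self.concentration_vector is not None:
            if len(self.concentration_vector) != len(self.species_list):
                raise ValueError("concentration_vector length must match species_list")
            if any(w <= 0 for w in self.concentration_vector):
                raise ValueError("Dirichlet weights must be positive")
        # 1.0 is allowed and deterministically zeroes every species
        if not 0.0 <= self.nd_probability <= 1.0:
            raise ValueError("nd_probability must lie in [0, 1]")


@dataclass(frozen=True)
class DoseSimSpec:
    """Recipe for one 4PL dose-response series."""

    seed: int
    doses: tuple[float, ...]
    ic50: float
    hill: float = 1.0
    bottom: float = 0.0
    top: float = 100.0
    noise_sd: float = 0.0
    unit: str = "mg/mL"

    def __post_init__(self) -> None:
        if not self.doses or any(x <= 0 for x in self.doses):
            raise ValueError("doses must be non-empty and strictly positive")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill slope must be positive")
        if self.bottom >= self.top:
            raise ValueError("bottom must be below top")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_profile(spec: ProfileSimSpec, sample_id: str = "sim") -> FattyAcidProfile:
    """Draw one random composition summing to 100% before N.D. zeroing."""
    rng = np.random.default_rng(spec.seed)
    weights = spec.concentration_vector or tuple(1.0 for _ in spec.species_list)
    fractions = rng.dirichlet(np.asarray(weights, dtype=float)) * 100.0
    detected = rng.random(len(spec.species_list)) >= spec.nd_probability
    entries = []
    for code, pct, keep in zip(spec.species_list, fractions, detected):
        d = parse_shorthand(code)
        if keep:
            entries.append(ProfileEntry(d, float(pct)))
        else:
            entries.append(ProfileEntry(d, 0.0, nd=True))
    with warnings.catch_warnings():
        # heavy N.D. zeroing legitimately drops the total below the
        # plausibility band; that is the point of the simulation knob
        warnings.simplefilter("ignore")
        return FattyAcidProfile(sample_id=sample_id, entries=tuple(entries))


def simulate_dose_response(spec: DoseSimSpec) -> DoseResponse:
    """Generate activities from the 4PL curve plus additive Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(sorted(spec.doses), dtype=float)
    act = four_param_logistic(doses, spec.bottom, spec.top, spec.ic50, spec.hill)
    if spec.noise_sd > 0:
        act = act + rng.normal(0.0, spec.noise_sd, size=doses.shape)
    return DoseResponse(tuple(float(x) for x in doses), tuple(float(a) for a in act),
                        unit=spec.unit)


def dose_response_to_plate(
    d: DoseResponse,
    a_control: float = 0.8,
    a_sample_blank: float = 0.05,
) -> list[tuple[float, str, AbsorbanceTriple]]:
    """Invert percent activity into plate absorbances (for plate-CSV output).

    Constructed so that ``scavenging_percent`` on each triple returns the
    original activity exactly.
    """
    rows = []
    for conc, pct in zip(d.concentrations, d.activities):
        # clamp at zero: very high noisy activities would need a negative
        # absorbance, which a plate cannot produce
        a_sample = max(a_sample_blank + a_control * (1.0 - pct / 100.0), 0.0)
        rows.append((conc, d.unit, AbsorbanceTriple(a_control, a_sample, a_sample_blank)))
    return rows


def reference_profiles() -> tuple[FattyAcidProfile, FattyAcidProfile]:
    """The two packaged diatom reference profiles (Ano, Rho).

    Verbatim transcription of the published GC-MS composition table:
    percentages of total FA with their reported SDs, N.D. entries kept as
    zero, lipid content (% w/w) attached as metadata.
    """
    out = []
    for sample_id, (fname, lipid) in _REFERENCE_FILES.items():
        ref = resources.files("lipidqi.data") / fname
        with resources.as_file(ref) as path:
            out.append(read_profile_csv(path, sample_id=sample_id, lipid_content=lipid))
    return tuple(out)
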