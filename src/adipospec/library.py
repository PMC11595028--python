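"""Pure-component band library for the synthetic adipocyte phantom.

Each cellular building block (a lipid species, a protein secondary-structure
pool, nucleic acids, cytochromes, sugars) is a :class:`ComponentSpectrum`: a
list of analytic bands per modality plus, for lipids, the functional-group
counts that drive the quantitative bands.

Lipid band areas follow a group-counting convention chosen so the two
classical calibrations are exactly linear on ideal spectra:

* the CH2 (IR 2852 cm^-1) and CH3 (IR 2954 cm^-1) stretching areas are
  proportional to the CH2 and CH3 group counts with a common cross-section,
  so the 2852/2954 ratio of a saturated triacylglycerol with N total acyl
  carbons is (N - 6)/3 = N/3 - 2;
* the C=C stretching area (Raman 1660 cm^-1) is proportional to the number
  of C=C bonds while the CH2 deformation area (Raman 1451 / IR 1465 cm^-1)
  is a fixed amount *per acyl chain*, so the 1660/1451 ratio equals the mean
  number of C=C bonds per acyl chain.

Acyl chains are modelled as esterified (the neutral-lipid pool of a lipid
droplet), so every chain also carries an ester C=O band at 1743 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

from .core import Modality, Spectrum, ValidationError, WavenumberAxis

__all__ = [
    "PureBand",
    "ComponentSpectrum",
    "lipid_component",
    "saturated_tag",
    "fatty_acid",
    "default_library",
    "build_component_spectrum",
    "compartment_spectrum",
    "mean_unsaturation",
    "mean_chain_length",
    "SATURATED_TAG_STANDARDS",
    "FATTY_ACID_SERIES",
    "library_to_yaml",
    "library_from_yaml",
]

_FWHM_G = 2.0 * np.sqrt(2.0 * np.log(2.0))

# unit band cross-sections (area units per functional group / per chain)
CH_STRETCH_AREA = 1.0          # per CH2 or CH3 group
CHAIN_DEFORMATION_AREA = 3.0   # per acyl chain (Raman 1451 / IR 1465)
CC_STRETCH_AREA = 3.0          # per C=C bond (Raman 1660)
ESTER_AREA_IR = 2.0            # per ester group (IR 1743)


@dataclass(frozen=True)
class PureBand:
    """One analytic band: center (cm^-1), FWHM (cm^-1), integrated area,
    shape in {gaussian, lorentzian, pseudo_voigt} with mixing ``eta`` and a
    ``role`` tag used by perturbation and attenuation machinery."""

    center: float
    fwhm: float
    area: float
    shape: str = "pseudo_voigt"
    eta: float = 0.5
    role: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("band FWHM must be positive")
        if self.area < 0:
            raise ValidationError("band area must be nonnegative")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValidationError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Band intensity on a grid; integrates to ``area`` analytically."""
        x = np.asarray(wavenumbers, dtype=float) - self.center
        sigma = self.fwhm / _FWHM_G
        gamma = self.fwhm / 2.0
        gauss = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        if self.shape == "gaussian":
            return self.area * gauss
        lorentz = (gamma / np.pi) / (x**2 + gamma**2)
        if self.shape == "lorentzian":
            return self.area * lorentz
        return self.area * (self.eta * lorentz + (1 - self.eta) * gauss)


@dataclass(frozen=True)
class ComponentSpectrum:
    """A named molecular component with per-modality band lists."""

    name: str
    raman_bands: tuple[PureBand, ...] = ()
    ftir_bands: tuple[PureBand, ...] = ()
    group_counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = dict(self.group_counts)
        if any(v < 0 for v in counts.values()):
            raise ValidationError("group counts must be nonnegative")
        if self.is_lipid and ("CH2" not in counts or "CH3" not in counts):
            raise ValidationError(
                f"lipid component {self.name!r} must define CH2 and CH3 counts"
            )
        object.__setattr__(self, "group_counts", counts)
        object.__setattr__(self, "raman_bands", tuple(self.raman_bands))
        object.__setattr__(self, "ftir_bands", tuple(self.ftir_bands))

    @property
    def is_lipid(self) -> bool:
        return "chain" in dict(self.group_counts)

    def bands(self, modality: Modality | str) -> tuple[PureBand, ...]:
        modality = Modality.coerce(modality)
        return self.raman_bands if modality is Modality.RAMAN else self.ftir_bands


def _positive(bands: Iterable[PureBand]) -> tuple[PureBand, ...]:
    return tuple(b for b in bands if b.area > 0)


def lipid_component(
    name: str,
    carbons: int,
    double_bonds: int,
    chains: int,
    *,
    shape: str = "pseudo_voigt",
    eta: float = 0.5,
    fwhm_raman: float = 12.0,
    fwhm_ftir: float = 20.0,
    extra_raman: Iterable[PureBand] = (),
    extra_ftir: Iterable[PureBand] = (),
) -> ComponentSpectrum:
    """Build a lipid component from its acyl-pool stoichiometry.

    ``carbons`` is the total acyl carbon count over all ``chains``; each chain
    contributes one CH3 and one carbonyl carbon, and each C=C bond replaces
    two CH2 groups, so CH2 = carbons - 2*chains - 2*double_bonds.
    """
    ch2 = carbons - 2 * chains - 2 * double_bonds
    if ch2 < 0:
        raise ValidationError(f"{name}: negative CH2 count from stoichiometry")
    counts = {
        "CH2": float(ch2),
        "CH3": float(chains),
        "C=C": float(double_bonds),
        "ester": float(chains),
        "chain": float(chains),
    }

    def rb(center, area, role):
        return PureBand(center, fwhm_raman, area, shape, eta, role)

    def ib(center, area, role):
        return PureBand(center, fwhm_ftir, area, shape, eta, role)

    raman = _positive(
        [
            rb(896.0, 0.2 * chains, "skeletal"),
            rb(1070.0, 0.5 * chains, "skeletal"),
            rb(1270.0, 0.8 * double_bonds, "C=C"),
            rb(1306.0, 1.0 * double_bonds, "C=C"),
            rb(1451.0, CHAIN_DEFORMATION_AREA * chains, "chain_deformation"),
            rb(1660.0, CC_STRETCH_AREA * double_bonds, "C=C"),
            rb(1743.0, 0.6 * chains, "ester"),
            rb(2855.0, CH_STRETCH_AREA * ch2, "CH2_stretch"),
            rb(2930.0, CH_STRETCH_AREA * chains, "CH3_stretch"),
            rb(3010.0, 1.5 * double_bonds, "C=C"),
        ]
    ) + _positive(extra_raman)
    ftir = _positive(
        [
            ib(1465.0, CHAIN_DEFORMATION_AREA * chains, "chain_deformation"),
            ib(1743.0, ESTER_AREA_IR * chains, "ester"),
            ib(2852.0, CH_STRETCH_AREA * ch2, "CH2_stretch"),
            ib(2954.0, CH_STRETCH_AREA * chains, "CH3_stretch"),
            ib(3010.0, 0.8 * double_bonds, "C=C"),
        ]
    ) + _positive(extra_ftir)
    return ComponentSpectrum(name, raman, ftir, counts)


#: saturated triacylglycerol calibration standards: name -> total acyl carbons
SATURATED_TAG_STANDARDS: dict[str, int] = {
    "tricaprylin": 24,
    "tricaprin": 30,
    "trilaurin": 36,
    "trimyristin": 42,
    "tripalmitin": 48,
    "tristearin": 54,
    "triarachidin": 60,
    "tribehenin": 66,
}

#: C18 fatty-acid unsaturation calibration series: name -> (carbons, C=C)
FATTY_ACID_SERIES: dict[str, tuple[int, int]] = {
    "stearic_acid": (18, 0),
    "oleic_acid": (18, 1),
    "linoleic_acid": (18, 2),
    "alpha_linolenic_acid": (18, 3),
}


def saturated_tag(total_carbons: int, *, shape: str = "gaussian") -> ComponentSpectrum:
    """Ideal saturated TAG standard with ``total_carbons`` acyl carbons.

    Gaussian bands by default: at the band separations involved the mutual
    overlap is below double precision, which keeps the chain-length
    calibration exactly linear.
    """
    if total_carbons % 3:
        raise ValidationError("saturated TAG needs a carbon count divisible by 3")
    return lipid_component(
        f"TAG_{total_carbons}_0", total_carbons, 0, 3, shape=shape
    )


def fatty_acid(
    carbons: int, double_bonds: int, *, shape: str = "gaussian"
) -> ComponentSpectrum:
    """Ideal single-chain fatty acid (acyl pool convention, see module doc)."""
    return lipid_component(
        f"FA_{carbons}_{double_bonds}", carbons, double_bonds, 1, shape=shape
    )


def _protein_alpha() -> ComponentSpectrum:
    return ComponentSpectrum(
        "protein_alpha",
        raman_bands=(
            PureBand(1003.0, 12, 1.5, role="protein"),
            PureBand(1257.0, 12, 2.0, role="protein"),
            PureBand(1657.0, 14, 6.0, role="amide_I"),
        ),
        ftir_bands=(
            PureBand(1396.0, 20, 1.5, role="protein"),
            PureBand(1545.0, 22, 5.0, role="amide_II"),
            PureBand(1655.0, 22, 8.0, role="amide_I"),
            PureBand(3290.0, 60, 6.0, role="amide_A"),
        ),
    )


def _protein_beta() -> ComponentSpectrum:
    return ComponentSpectrum(
        "protein_beta",
        raman_bands=(
            PureBand(1003.0, 12, 1.0, role="protein"),
            PureBand(1235.0, 12, 2.0, role="protein"),
            PureBand(1670.0, 14, 6.0, role="amide_I"),
        ),
        ftir_bands=(
            PureBand(1545.0, 22, 4.0, role="amide_II"),
            PureBand(1620.0, 18, 6.0, role="amide_I"),
            PureBand(1680.0, 16, 3.0, role="amide_I"),
            PureBand(3290.0, 60, 5.0, role="amide_A"),
        ),
    )


def _nucleic_acid() -> ComponentSpectrum:
    return ComponentSpectrum(
        "nucleic_acid",
        raman_bands=(
            PureBand(790.0, 12, 3.0, role="nucleic"),
            PureBand(1095.0, 12, 1.5, role="nucleic"),
            PureBand(1240.0, 14, 1.0, role="nucleic"),
            PureBand(1340.0, 12, 1.0, role="nucleic"),
            PureBand(1375.0, 12, 0.8, role="nucleic"),
            PureBand(1575.0, 12, 1.2, role="nucleic"),
        ),
        ftir_bands=(
            PureBand(1080.0, 20, 3.0, role="nucleic"),
            PureBand(1240.0, 24, 1.5, role="nucleic"),
        ),
    )


def _cytochrome() -> ComponentSpectrum:
    # resonance-enhanced heme bands; essentially a Raman-only marker
    return ComponentSpectrum(
        "cytochrome",
        raman_bands=(
            PureBand(750.0, 10, 3.0, role="cytochrome"),
            PureBand(1316.0, 12, 2.5, role="cytochrome"),
            PureBand(1585.0, 12, 3.5, role="cytochrome"),
        ),
        ftir_bands=(),
    )


def _sugar() -> ComponentSpectrum:
    return ComponentSpectrum(
        "sugar",
        raman_bands=(PureBand(1126.0, 14, 0.8, role="sugar"),),
        ftir_bands=(
            PureBand(1050.0, 24, 2.5, role="sugar"),
            PureBand(1114.0, 20, 1.5, role="sugar"),
            PureBand(1150.0, 18, 1.2, role="sugar"),
        ),
    )


def default_library() -> dict[str, ComponentSpectrum]:
    """The built-in component library used by the phantom generator."""
    pl_extra_raman = (
        PureBand(1099.0, 12, 0.8, role="phospholipid"),
        PureBand(1129.0, 12, 1.0, role="phospholipid"),
    )
    pl_extra_ftir = (
        PureBand(1240.0, 24, 1.5, role="phospholipid"),
        PureBand(1340.0, 20, 1.0, role="phospholipid"),
    )
    ce_extra_raman = (PureBand(605.0, 12, 1.5, role="cholesteryl_ester"),)
    ce_extra_ftir = (PureBand(1178.0, 18, 2.0, role="cholesteryl_ester"),)
    components = [
        lipid_component("SFA_18_0", 18, 0, 1),
        lipid_component("SFA_16_0", 16, 0, 1),
        lipid_component("MUFA_18_1", 18, 1, 1),
        lipid_component("TAG_48_1", 48, 1, 3),
        lipid_component("CE_14_1", 14, 1, 1,
                        extra_raman=ce_extra_raman, extra_ftir=ce_extra_ftir),
        lipid_component("PL_34_1", 34, 1, 2,
                        extra_raman=pl_extra_raman, extra_ftir=pl_extra_ftir),
        _protein_alpha(),
        _protein_beta(),
        _nucleic_acid(),
        _cytochrome(),
        _sugar(),
    ]
    return {c.name: c for c in components}


def build_component_spectrum(
    component: ComponentSpectrum,
    axis: WavenumberAxis,
    modality: Modality | str,
    band_scale: Mapping[str, float] | None = None,
) -> Spectrum:
    """Render a component onto an axis as the sum of its analytic bands.

    ``band_scale`` maps band roles to multiplicative factors (used by the
    fixative-perturbation machinery); unknown roles scale by 1.
    """
    modality = Modality.coerce(modality)
    total = np.zeros(len(axis))
    for band in component.bands(modality):
        if not (axis.low <= band.center <= axis.high):
            raise ValidationError(
                f"{component.name}: band at {band.center} cm^-1 outside axis "
                f"range [{axis.low}, {axis.high}]"
            )
        factor = 1.0 if band_scale is None else float(band_scale.get(band.role, 1.0))
        total += factor * band.profile(axis.values)
    return Spectrum(axis, total, modality)


def compartment_spectrum(
    composition: Mapping[str, float],
    library: Mapping[str, ComponentSpectrum],
    axis: WavenumberAxis,
    modality: Modality | str,
    band_scale: Mapping[str, float] | None = None,
) -> Spectrum:
    """Mole-fraction-weighted sum of component spectra for one compartment."""
    total = np.zeros(len(axis))
    for name, fraction in composition.items():
        if name not in library:
            raise KeyError(f"component {name!r} missing from library")
        total += fraction * build_component_spectrum(
            library[name], axis, modality, band_scale
        ).intensities
    return Spectrum(axis, total, Modality.coerce(modality))


def _lipid_moments(
    composition: Mapping[str, float], library: Mapping[str, ComponentSpectrum]
) -> tuple[float, float, float]:
    chains = bonds = carbons = 0.0
    for name, fraction in composition.items():
        counts = dict(library[name].group_counts)
        if "chain" not in counts:
            continue
        chains += fraction * counts["chain"]
        bonds += fraction * counts.get("C=C", 0.0)
        carbons += fraction * (
            counts["CH2"] + counts["CH3"] + 2 * counts.get("C=C", 0.0)
            + counts.get("ester", 0.0)
        )
    return chains, bonds, carbons


def mean_unsaturation(
    composition: Mapping[str, float], library: Mapping[str, ComponentSpectrum]
) -> float:
    """Mean number of C=C bonds per acyl chain of a lipid composition."""
    chains, bonds, _ = _lipid_moments(composition, library)
    if chains == 0:
        raise ValidationError("composition has no acyl chains")
    return bonds / chains


def mean_chain_length(
    composition: Mapping[str, float], library: Mapping[str, ComponentSpectrum]
) -> float:
    """Mean acyl carbon count per chain of a lipid composition."""
    chains, _, carbons = _lipid_moments(composition, library)
    if chains == 0:
        raise ValidationError("composition has no acyl chains")
    return carbons / chains


# ------------------------------------------------------------- YAML export

def library_to_yaml(library: Mapping[str, ComponentSpectrum]) -> str:
    payload = {}
    for name, comp in library.items():
        payload[name] = {
            "group_counts": dict(comp.group_counts),
            "raman_bands": [
                {"center": b.center, "fwhm": b.fwhm, "area": b.area,
                 "shape": b.shape, "eta": b.eta, "role": b.role}
                for b in comp.raman_bands
            ],
            "ftir_bands": [
                {"center": b.center, "fwhm": b.fwhm, "area": b.area,
                 "shape": b.shape, "eta": b.eta, "role": b.role}
                for b in comp.ftir_bands
            ],
        }
    return yaml.safe_dump({"version": 1, "components": payload}, sort_keys=True)


def library_from_yaml(text: str) -> dict[str, ComponentSpectrum]:
    payload = yaml.safe_load(text)
    library = {}
    for name, entry in payload["components"].items():
        library[name] = ComponentSpectrum(
            name,
            tuple(PureBand(**b) for b in entry.get("raman_bands", [])),
            tuple(PureBand(**b) for b in entry.get("ftir_bands", [])),
            entry.get("group_counts", {}),
        )
    return library
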