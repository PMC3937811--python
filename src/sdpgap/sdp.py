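"""Scattering density profile (SDP) model of a fluid lipid bilayer.

The bilayer is parsed into quasi-molecular fragments -- choline methyls
(CholCH3), phosphate + CH2CH2N (PCN), carbonyl + glycerol (CG), chain
methylenes (CH2, with methine CH pooled in) and terminal methyls (CH3) --
each described by a volume probability distribution P_i(z) across the
bilayer normal.  Headgroup fragments are mirrored Gaussian pairs, the
hydrocarbon core is an error-function envelope of unit height, CH2 is the
envelope minus the terminal-methyl Gaussian, and water fills whatever is
left (spatial conservation: sum_i P_i + P_W = 1).

Scaling each P_i by the fragment's electron density (X-rays) or neutron
scattering length density turns the profile into a contrast profile
Delta-rho(z) whose cosine transform is the bilayer form factor F(q),
evaluated here in closed form.

Units: lengths in angstrom, volumes in A^3, electron densities in e/A^3,
neutron SLDs in A^-2, q in 1/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "ATOMIC_NUMBERS",
    "COHERENT_B",
    "WATER_VOLUME",
    "Component",
    "ParsingScheme",
    "Contrast",
    "BilayerSDP",
    "component_density",
    "solvent_density",
    "hydrocarbon_envelope",
    "gaussian_pair",
    "volume_profiles",
    "water_profile",
    "form_factor",
    "electron_density_profile",
    "default_pc_scheme",
]

# ---------------------------------------------------------------------------
# Atomic constants
# ---------------------------------------------------------------------------

#: Atomic numbers (electrons per atom).  Deuterium is listed separately so a
#: composition can carry protiated and deuterated hydrogens side by side.
ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "P": 15}

#: Bound coherent neutron scattering lengths, fm (1 fm = 1e-5 A).
COHERENT_B: dict[str, float] = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
}

FM_TO_A = 1.0e-5

#: Molecular volume of water near physiological temperature, A^3.
WATER_VOLUME = 30.0

#: Choline-methyl Gaussian width, fixed by convention (A).
SIGMA_CHOLCH3 = 2.98

#: Headgroup (CholCH3 + PCN + CG) volume target, A^3.
HEADGROUP_VOLUME_TARGET = 331.0

#: Condensed volume of cholesterol inside a bilayer, A^3.
CHOLESTEROL_VOLUME = 630.0

CHOLESTEROL_COMPOSITION = {"C": 27, "H": 46, "O": 1}


def _sum_electrons(composition: dict[str, float]) -> float:
    try:
        return float(sum(ATOMIC_NUMBERS[el] * n for el, n in composition.items()))
    except KeyError as exc:  # pragma: no cover - message matters, not path
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from None


def _sum_b(composition: dict[str, float]) -> float:
    """Coherent scattering length of a composition, in angstrom."""
    try:
        return sum(COHERENT_B[el] * n for el, n in composition.items()) * FM_TO_A
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """One quasi-molecular fragment of the parsing scheme.

    ``composition`` counts atoms per lipid for the whole fragment pool (e.g.
    the CH2 component of POPC pools both chains' methylenes and methines),
    with "H" and "D" held separately.  ``volume_ref`` is the reference
    fragment volume per lipid, and ``volume_tolerance`` the admitted
    fractional variation around it during fitting.

    ``role`` places the fragment in the model: "headgroup" fragments are
    Gaussian pairs, "ch2"/"ch3" build the hydrocarbon core, and "ch_merge"
    fragments are pooled into CH2 when the scheme is normalised.
    """

    name: str
    composition: dict[str, float]
    volume_ref: float
    role: str = "headgroup"
    volume_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.volume_ref <= 0:
            raise ValueError(f"{self.name}: volume_ref must be positive")
        if not 0 <= self.volume_tolerance < 1:
            raise ValueError(f"{self.name}: volume_tolerance must be in [0, 1)")
        if any(n < 0 for n in self.composition.values()):
            raise ValueError(f"{self.name}: negative element count")
        _sum_electrons(self.composition)  # validates symbols

    @property
    def electrons(self) -> float:
        return _sum_electrons(self.composition)


@dataclass(frozen=True)
class Contrast:
    """Radiation type plus solvent and deuteration context of one dataset.

    For neutrons the solvent scattering length density follows from the
    H2O/D2O mixing ratio ``solvent_d2o_fraction`` unless an explicit
    ``solvent_density`` override is given.  ``deuteration`` maps component
    names to the number of chain hydrogens replaced by deuterium per lipid
    (e.g. ``{"CH2": 28, "CH3": 3}`` for an sn-1 perdeuterated palmitoyl
    chain), applied on top of the component composition.
    """

    radiation: str = "xray"
    solvent_d2o_fraction: float = 0.0
    solvent_density: float | None = None
    deuteration: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radiation not in ("xray", "neutron"):
            raise ValueError(f"radiation must be 'xray' or 'neutron', got {self.radiation!r}")
        if not 0.0 <= self.solvent_d2o_fraction <= 1.0:
            raise ValueError("solvent_d2o_fraction must lie in [0, 1]")
        if self.solvent_density is not None:
            if not math.isfinite(self.solvent_density):
                raise ValueError("solvent_density must be finite")
            if self.radiation == "xray" and self.solvent_density <= 0:
                raise ValueError("X-ray solvent electron density must be positive")


@dataclass(frozen=True)
class ParsingScheme:
    """Ordered fragment definitions plus scheme-level constraint targets.

    Exactly one component must carry the "ch2" role and one the "ch3" role;
    any "ch_merge" components (an explicit methine fragment, say) are pooled
    into CH2 on construction via :meth:`normalized`.  An optional cholesterol
    admixture ``(mole fraction x_c, volume V_chol)`` is merged into the CH2
    distribution, reflecting cholesterol's hydrophobic placement.
    """

    components: tuple[Component, ...]
    headgroup_volume_target: float = HEADGROUP_VOLUME_TARGET
    cholesterol_fraction: float = 0.0
    cholesterol_volume: float = CHOLESTEROL_VOLUME
    cholesterol_composition: dict[str, float] = field(
        default_factory=lambda: dict(CHOLESTEROL_COMPOSITION)
    )

    def __post_init__(self) -> None:
        if self.headgroup_volume_target <= 0:
            raise ValueError("headgroup_volume_target must be positive")
        if not 0.0 <= self.cholesterol_fraction < 1.0:
            raise ValueError("cholesterol_fraction must lie in [0, 1)")
        roles = [c.role for c in self.components]
        if roles.count("ch2") != 1 or roles.count("ch3") != 1:
            raise ValueError("scheme needs exactly one 'ch2' and one 'ch3' component")

    def normalized(self) -> "ParsingScheme":
        """Pool every 'ch_merge' component into CH2 (volumes and atoms add)."""
        merges = [c for c in self.components if c.role == "ch_merge"]
        if not merges:
            return self
        out: list[Component] = []
        for c in self.components:
            if c.role == "ch_merge":
                continue
            if c.role == "ch2":
                comp = dict(c.composition)
                vol = c.volume_ref
                for m in merges:
                    for el, n in m.composition.items():
                        comp[el] = comp.get(el, 0) + n
                    vol += m.volume_ref
                c = replace(c, composition=comp, volume_ref=vol)
            out.append(c)
        return replace(self, components=tuple(out))

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def headgroup_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.role == "headgroup")

    @property
    def ch2(self) -> Component:
        return next(c for c in self.components if c.role == "ch2")

    @property
    def ch3(self) -> Component:
        return next(c for c in self.components if c.role == "ch3")

    @property
    def chol_ratio(self) -> float:
        """Cholesterol molecules per lipid, x_c / (1 - x_c)."""
        x = self.cholesterol_fraction
        return x / (1.0 - x)


@dataclass
class BilayerSDP:
    """Free structural state of one (symmetric) bilayer, half-bilayer frame.

    z = 0 is the bilayer midplane; the terminal-methyl Gaussian is pinned
    there by symmetry.  ``D_C`` is the half hydrocarbon thickness (the
    position of the chain error function) and ``volumes`` holds per-lipid
    fragment volumes keyed by component name.  The lateral area per lipid is
    not independent: A = V_HC / D_C, with V_HC the hydrocarbon volume
    (CH2 + CH3, plus the cholesterol share when merged).
    """

    z_CholCH3: float
    z_PCN: float
    z_CG: float
    sigma_PCN: float
    sigma_CG: float
    sigma_CH3: float
    D_C: float
    sigma_HC: float
    volumes: dict[str, float]
    V_L: float
    sigma_CholCH3: float = SIGMA_CHOLCH3

    def __post_init__(self) -> None:
        for name in ("sigma_CholCH3", "sigma_PCN", "sigma_CG", "sigma_CH3", "sigma_HC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.D_C <= 0:
            raise ValueError("D_C must be positive")
        if self.V_L <= 0:
            raise ValueError("V_L must be positive")

    def center(self, name: str) -> float:
        if name == "CholCH3":
            return self.z_CholCH3
        if name == "PCN":
            return self.z_PCN
        if name == "CG":
            return self.z_CG
        raise KeyError(name)

    def width(self, name: str) -> float:
        return {
            "CholCH3": self.sigma_CholCH3,
            "PCN": self.sigma_PCN,
            "CG": self.sigma_CG,
            "CH3": self.sigma_CH3,
        }[name]

    def hydrocarbon_volume(self, scheme: ParsingScheme) -> float:
        """Per-lipid hydrocarbon volume incl. the merged cholesterol share."""
        v = self.volumes[scheme.ch2.name] + self.volumes[scheme.ch3.name]
        return v + scheme.chol_ratio * scheme.cholesterol_volume

    def area(self, scheme: ParsingScheme) -> float:
        """Lateral area per lipid implied by the chain region, A^2."""
        return self.hydrocarbon_volume(scheme) / self.D_C


# ---------------------------------------------------------------------------
# Scattering densities
# ---------------------------------------------------------------------------


def _effective_composition_volume(
    c: Component, scheme: ParsingScheme, contrast: Contrast
) -> tuple[dict[str, float], float]:
    """Composition and volume of a fragment after deuteration and, for the
    CH2 fragment, cholesterol merging."""
    comp = dict(c.composition)
    vol = c.volume_ref
    n_d = contrast.deuteration.get(c.name, 0.0)
    if n_d:
        if n_d > comp.get("H", 0.0):
            raise ValueError(
                f"{c.name}: deuteration of {n_d} exceeds {comp.get('H', 0)} hydrogens"
            )
        comp["H"] = comp.get("H", 0.0) - n_d
        comp["D"] = comp.get("D", 0.0) + n_d
    if c.role == "ch2" and scheme.cholesterol_fraction > 0:
        r = scheme.chol_ratio
        for el, n in scheme.cholesterol_composition.items():
            comp[el] = comp.get(el, 0.0) + r * n
        vol += r * scheme.cholesterol_volume
    return comp, vol


def component_density(
    c: Component,
    contrast: Contrast,
    scheme: ParsingScheme | None = None,
    volume: float | None = None,
) -> float:
    """Scattering density of one fragment.

    X-rays: total electrons / volume (e/A^3).  Neutrons: summed coherent
    scattering lengths / volume (A^-2), with H->D substitution applied per
    the contrast's deuteration spec.  ``volume`` overrides the reference
    volume (used during fitting where fragment volumes are free); when the
    scheme merges cholesterol, the CH2 density uses the pooled
    composition + volume so the override refers to the bare CH2 volume.
    """
    scheme_eff = scheme if scheme is not None else _BARE_SCHEME
    comp, vol = _effective_composition_volume(c, scheme_eff, contrast)
    if volume is not None:
        extra = vol - c.volume_ref  # cholesterol share, if any
        vol = volume + extra
    if contrast.radiation == "xray":
        return _sum_electrons(comp) / vol
    return _sum_b(comp) / vol


class _Bare:
    cholesterol_fraction = 0.0
    chol_ratio = 0.0


_BARE_SCHEME = _Bare()  # sentinel for density queries outside a scheme


def solvent_density(contrast: Contrast, water_volume: float = WATER_VOLUME) -> float:
    """Scattering density of the aqueous phase (e/A^3 or A^-2)."""
    if contrast.solvent_density is not None:
        return contrast.solvent_density
    if contrast.radiation == "xray":
        return 10.0 / water_volume
    f = contrast.solvent_d2o_fraction
    b = 2.0 * ((1.0 - f) * COHERENT_B["H"] + f * COHERENT_B["D"]) + COHERENT_B["O"]
    return b * FM_TO_A / water_volume


# ---------------------------------------------------------------------------
# Volume probability distributions
# ---------------------------------------------------------------------------


def hydrocarbon_envelope(z, D_C: float, sigma_HC: float):
    """Unit-height error-function envelope of the hydrocarbon core.

    0.5 * [erf((z + D_C)/(sqrt(2) s)) - erf((z - D_C)/(sqrt(2) s))]:
    symmetric in z, value 1/2 at z = +-D_C, integrates to exactly 2 D_C.
    """
    if D_C <= 0 or sigma_HC <= 0:
        raise ValueError("D_C and sigma_HC must be positive")
    s = math.sqrt(2.0) * sigma_HC
    z = np.asarray(z, dtype=float)
    return 0.5 * (erf((z + D_C) / s) - erf((z - D_C) / s))


def gaussian_pair(z, center: float, width: float, area_per_leaflet: float):
    """Mirrored Gaussian pair at +-center, each leaflet integrating to
    ``area_per_leaflet`` (= V_i / A for a headgroup fragment).  A center of
    zero collapses the pair onto a single peak of doubled amplitude."""
    if width <= 0:
        raise ValueError("width must be positive")
    if area_per_leaflet < 0:
        raise ValueError("area_per_leaflet must be non-negative")
    z = np.asarray(z, dtype=float)
    amp = area_per_leaflet / (width * math.sqrt(2.0 * math.pi))
    return amp * (
        np.exp(-((z - center) ** 2) / (2.0 * width**2))
        + np.exp(-((z + center) ** 2) / (2.0 * width**2))
    )


def volume_profiles(
    sdp: BilayerSDP, scheme: ParsingScheme, z_grid
) -> dict[str, np.ndarray]:
    """Per-component volume probability profiles on ``z_grid``.

    Returns a dict keyed by component name.  CH3 is the central Gaussian
    (total area 2 V_CH3/A), CH2 the chain envelope minus CH3 (cholesterol
    volume rides inside the envelope via the area normalisation when
    merged), and each headgroup fragment a mirrored Gaussian pair of leaflet
    area V_i/A.  A negative CH2 anywhere marks an infeasible parameter set;
    it is returned as-is for the penalty system, never clipped.
    """
    z = np.asarray(z_grid, dtype=float)
    A = sdp.area(scheme)
    out: dict[str, np.ndarray] = {}
    env = hydrocarbon_envelope(z, sdp.D_C, sdp.sigma_HC)
    ch3 = gaussian_pair(z, 0.0, sdp.sigma_CH3, sdp.volumes[scheme.ch3.name] / A)
    out[scheme.ch3.name] = ch3
    out[scheme.ch2.name] = env - ch3
    for c in scheme.components:
        if c.role != "headgroup":
            continue
        out[c.name] = gaussian_pair(
            z, sdp.center(c.name), sdp.width(c.name), sdp.volumes[c.name] / A
        )
    return out


def water_profile(profiles: dict[str, np.ndarray], z_grid=None) -> np.ndarray:
    """Water volume probability by spatial conservation: P_W = 1 - sum_i P_i.

    Exact complement at every grid point; negative excursions are returned
    untouched so the penalty system can flag them.
    """
    total = None
    for p in profiles.values():
        total = p.copy() if total is None else total + p
    if total is None:
        raise ValueError("no component profiles given")
    return 1.0 - total


# ---------------------------------------------------------------------------
# Form factor
# ---------------------------------------------------------------------------


def _component_densities(
    sdp: BilayerSDP, scheme: ParsingScheme, contrast: Contrast
) -> dict[str, float]:
    return {
        c.name: component_density(c, contrast, scheme, volume=sdp.volumes[c.name])
        for c in scheme.components
    }


def form_factor(q_grid, sdp: BilayerSDP, scheme: ParsingScheme, contrast: Contrast):
    """Analytic bilayer form factor F(q), the cosine transform of the
    solvent-subtracted density profile Delta-rho(z) = sum_i (rho_i - rho_W) P_i(z).

    Gaussian pair -> 2 a_i (rho_i - rho_W) cos(q z_i) exp(-sigma_i^2 q^2 / 2);
    chain envelope -> (rho_CH2 - rho_W) (2 sin(q D_C)/q) exp(-sigma_HC^2 q^2/2)
    (q -> 0 limit 2 D_C), the central CH3 Gaussian carrying the density
    difference rho_CH3 - rho_CH2 on top of the envelope.  Real-valued by
    bilayer symmetry.  Units: e/A^2 for X-rays, 1/A for neutrons.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    A = sdp.area(scheme)
    rho = _component_densities(sdp, scheme, contrast)
    rho_w = solvent_density(contrast)

    with np.errstate(invalid="ignore", divide="ignore"):
        env_ft = np.where(
            q > 0, 2.0 * np.sin(q * sdp.D_C) / np.where(q > 0, q, 1.0), 2.0 * sdp.D_C
        ) * np.exp(-(sdp.sigma_HC**2) * q**2 / 2.0)

    F = (rho[scheme.ch2.name] - rho_w) * env_ft
    # CH3 Gaussian replaces CH2 inside the envelope
    a_ch3 = sdp.volumes[scheme.ch3.name] / A
    F = F + (
        (rho[scheme.ch3.name] - rho[scheme.ch2.name])
        * 2.0
        * a_ch3
        * np.exp(-(sdp.sigma_CH3**2) * q**2 / 2.0)
    )
    for c in scheme.components:
        if c.role != "headgroup":
            continue
        a_i = sdp.volumes[c.name] / A
        F = F + (
            (rho[c.name] - rho_w)
            * 2.0
            * a_i
            * np.cos(q * sdp.center(c.name))
            * np.exp(-(sdp.width(c.name) ** 2) * q**2 / 2.0)
        )
    return F


def electron_density_profile(
    sdp: BilayerSDP, scheme: ParsingScheme, z_grid, contrast: Contrast | None = None
) -> np.ndarray:
    """Total scattering density profile rho(z) = sum_i rho_i P_i + rho_W P_W
    (the head-to-head thickness D_HH is read off its maxima)."""
    if contrast is None:
        contrast = Contrast(radiation="xray")
    profiles = volume_profiles(sdp, scheme, z_grid)
    rho = _component_densities(sdp, scheme, contrast)
    pw = water_profile(profiles)
    total = solvent_density(contrast) * pw
    for name, p in profiles.items():
        total = total + rho[name] * p
    return total


# ---------------------------------------------------------------------------
# Default phosphatidylcholine parsing schemes
# ---------------------------------------------------------------------------

#: Reference fragment volumes per group, A^3 (fluid-phase PC literature scale).
_V_CH2_UNIT = 28.1
_V_CH3_UNIT = 54.0


def default_pc_scheme(
    n_CH2: int = 28,
    n_CH: int = 0,
    n_CH3: int = 2,
    cholesterol_fraction: float = 0.0,
    volume_tolerance: float = 0.05,
) -> ParsingScheme:
    """Standard five-fragment phosphatidylcholine parsing scheme.

    ``n_CH2``/``n_CH``/``n_CH3`` count methylenes, methines and terminal
    methyls over both acyl chains; methines are pooled into the CH2
    fragment (their contrast against CH2 is negligible even for neutrons).
    DPPC: n_CH2=28, n_CH=0; POPC: n_CH2=28, n_CH=2.
    """
    components = [
        Component(
            "CholCH3", {"C": 3, "H": 9}, 98.9, "headgroup", volume_tolerance
        ),
        Component(
            "PCN", {"C": 2, "H": 4, "N": 1, "O": 4, "P": 1}, 126.9, "headgroup",
            volume_tolerance,
        ),
        # glycerol backbone C3H5O2 plus both acyl carbonyls (C=O)
        Component(
            "CG", {"C": 5, "H": 5, "O": 4}, 105.2, "headgroup", volume_tolerance
        ),
        Component(
            "CH2", {"C": n_CH2, "H": 2 * n_CH2}, _V_CH2_UNIT * n_CH2, "ch2",
            volume_tolerance,
        ),
        Component(
            "CH3", {"C": n_CH3, "H": 3 * n_CH3}, _V_CH3_UNIT * n_CH3, "ch3",
            volume_tolerance,
        ),
    ]
    if n_CH:
        # explicit methines, pooled into CH2 by normalized()
        components.append(
            Component("CH", {"C": n_CH, "H": n_CH}, 21.0 * n_CH, "ch_merge",
                      volume_tolerance)
        )
    return ParsingScheme(
        components=tuple(components),
        cholesterol_fraction=cholesterol_fraction,
    ).normalized()
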