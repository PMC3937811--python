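"""Synthetic SAXS/SANS curve generation from known ground truth.

Evaluates the exact forward model (SDP form factor + MCT lattice) for a
known bilayer state, adds multiplicative Gaussian noise emulating counting
statistics after radial averaging, and optionally writes the 3-column
``.dat`` files plus a YAML truth sidecar.  A library of named presets
emulates the lipid systems this class of experiment is run on (saturated
and monounsaturated phosphatidylcholines, cholesterol admixtures, and a
protiated/chain-perdeuterated neutron contrast pair); preset values sit at
realistic fluid-phase magnitudes and encode the physical orderings
(cholesterol stiffens the stack, hence a smaller fluctuation parameter),
not any particular measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import Dataset, penalty
from .lattice import InstrumentModel, LatticeParams, caille_structure_factor, intensity_mlv, intensity_ulv
from .sdp import BilayerSDP, Contrast, ParsingScheme, default_pc_scheme, form_factor

__all__ = ["DatasetSpec", "TruthSpec", "generate", "scenario_library"]


@dataclass
class DatasetSpec:
    """Acquisition settings of one synthetic curve."""

    name: str
    geometry: str = "mlv"  # mlv | ulv
    contrast: Contrast = field(default_factory=Contrast)
    lattice: LatticeParams | None = None
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    q_min: float = 0.03
    q_max: float = 0.8
    n_points: int = 400
    sigma_rel: float = 0.01
    sigma_abs: float = 0.0

    def __post_init__(self) -> None:
        if self.q_min <= 0:
            raise ValueError("q_min must be positive")
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise ValueError("noise fractions must be non-negative")
        if self.geometry == "mlv" and self.lattice is None:
            raise ValueError(f"{self.name}: MLV geometry needs lattice parameters")


@dataclass
class TruthSpec:
    """Ground-truth bilayer plus the list of curves to synthesise from it."""

    sdp: BilayerSDP
    scheme: ParsingScheme
    datasets: list[DatasetSpec]
    V_L: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V_L == 0.0:
            self.V_L = self.sdp.V_L


def forward_curve(truth: TruthSpec, spec: DatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free model intensity of one dataset spec."""
    q = np.linspace(spec.q_min, spec.q_max, spec.n_points)
    F = form_factor(q, truth.sdp, truth.scheme, spec.contrast)
    if spec.geometry == "mlv":
        S = caille_structure_factor(q, spec.lattice)
        I = intensity_mlv(q, F, S, spec.lattice, spec.instrument)
    else:
        I = intensity_ulv(q, F, spec.instrument)
    return q, I


def generate(
    truth: TruthSpec, seed: int | None = None, out_dir=None
) -> list[Dataset]:
    """Synthesise all curves of a truth spec.

    Noise model: I_noisy = I (1 + eps), eps ~ N(0, sigma_rel^2), with the
    reported uncertainty sigma = sigma_rel * |I| + sigma_abs.  Deterministic
    for a given seed.  Refuses infeasible truths (nonzero constraint
    penalty, e.g. negative water probability).
    """
    pen = penalty(truth.sdp, truth.scheme)
    if pen != 0.0:
        raise ValueError(
            f"infeasible truth: constraint penalty {pen:g} "
            "(check headgroup volumes and profile positivity)"
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    datasets: list[Dataset] = []
    for spec in truth.datasets:
        q, I = forward_curve(truth, spec)
        sigma = spec.sigma_rel * np.abs(I) + spec.sigma_abs
        if spec.sigma_rel == 0.0 and spec.sigma_abs == 0.0:
            I_noisy = I
            sigma = np.full_like(I, max(1e-12, 1e-6 * float(np.abs(I).max())))
        else:
            I_noisy = I * (1.0 + rng.normal(0.0, spec.sigma_rel, I.size))
        datasets.append(
            Dataset(
                q=q,
                I=I_noisy,
                sigma=sigma,
                geometry=spec.geometry,
                contrast=spec.contrast,
                name=spec.name,
                beam_sigma=spec.instrument.beam_sigma,
            )
        )
    if out_dir is not None:
        _write(truth, datasets, out_dir)
    return datasets


def _write(truth: TruthSpec, datasets: list[Dataset], out_dir) -> None:
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        arr = np.column_stack([ds.q, ds.I, ds.sigma])
        header = f"synthetic curve '{ds.name}' ({ds.geometry}, {ds.contrast.radiation})"
        np.savetxt(out / f"{ds.name}.dat", arr, header=header)
    sidecar = {
        "sdp": {
            "z_CholCH3": truth.sdp.z_CholCH3,
            "z_PCN": truth.sdp.z_PCN,
            "z_CG": truth.sdp.z_CG,
            "sigma_CholCH3": truth.sdp.sigma_CholCH3,
            "sigma_PCN": truth.sdp.sigma_PCN,
            "sigma_CG": truth.sdp.sigma_CG,
            "sigma_CH3": truth.sdp.sigma_CH3,
            "sigma_HC": truth.sdp.sigma_HC,
            "D_C": truth.sdp.D_C,
            "V_L": truth.sdp.V_L,
            "volumes": dict(truth.sdp.volumes),
        },
        "datasets": [
            {
                "name": s.name,
                "geometry": s.geometry,
                "radiation": s.contrast.radiation,
                "lattice": None
                if s.lattice is None
                else {
                    "d": s.lattice.d,
                    "N": s.lattice.N,
                    "eta": s.lattice.eta,
                    "N_diff": s.lattice.N_diff,
                },
            }
            for s in truth.datasets
        ],
        "seed": truth.seed,
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def _popc_sdp() -> tuple[BilayerSDP, ParsingScheme]:
    """Fluid-phase POPC-like bilayer (303 K scale): A ~ 65 A^2, D_C ~ 14.3 A."""
    scheme = default_pc_scheme(n_CH2=28, n_CH=2, n_CH3=2)
    volumes = {c.name: c.volume_ref for c in scheme.components}
    v_l = sum(volumes.values())  # fragments tile the whole lipid
    sdp = BilayerSDP(
        z_CholCH3=20.2,
        z_PCN=18.6,
        z_CG=15.2,
        sigma_PCN=2.6,
        sigma_CG=2.2,
        sigma_CH3=2.9,
        D_C=14.32,
        sigma_HC=2.3,
        volumes=volumes,
        V_L=v_l,
    )
    return sdp, scheme


def _dppc_sdp() -> tuple[BilayerSDP, ParsingScheme]:
    """Fluid-phase DPPC-like bilayer (323 K scale): A ~ 63 A^2, D_C ~ 14.2 A."""
    scheme = default_pc_scheme(n_CH2=28, n_CH=0, n_CH3=2)
    volumes = {c.name: c.volume_ref for c in scheme.components}
    v_l = sum(volumes.values())
    sdp = BilayerSDP(
        z_CholCH3=20.4,
        z_PCN=19.0,
        z_CG=15.2,
        sigma_PCN=2.5,
        sigma_CG=2.2,
        sigma_CH3=2.9,
        D_C=14.18,
        sigma_HC=2.3,
        volumes=volumes,
        V_L=v_l,
    )
    return sdp, scheme


def _popc_chol_sdp() -> tuple[BilayerSDP, ParsingScheme]:
    """POPC + 20 mol% cholesterol, merged-CH2 scheme: condensation thickens
    the chain region and damps bending fluctuations."""
    scheme = default_pc_scheme(n_CH2=28, n_CH=2, n_CH3=2, cholesterol_fraction=0.2)
    volumes = {c.name: c.volume_ref for c in scheme.components}
    v_l = sum(volumes.values())
    sdp = BilayerSDP(
        z_CholCH3=22.2,
        z_PCN=21.0,
        z_CG=18.2,
        sigma_PCN=2.6,
        sigma_CG=2.4,
        sigma_CH3=2.9,
        D_C=17.1,
        sigma_HC=2.4,
        volumes=volumes,
        V_L=v_l,
    )
    return sdp, scheme


_D31 = {"CH2": 28.0, "CH3": 3.0}  # sn-1 palmitoyl-d31: 14 CD2 + CD3

_SAXS_GRID = dict(q_min=0.03, q_max=0.8, n_points=400)
_SANS_GRID = dict(q_min=0.01, q_max=0.3, n_points=150)


def scenario_library() -> dict[str, TruthSpec]:
    """Named ground-truth presets.

    - ``dppc_saxs_mlv`` / ``popc_saxs_mlv``: standalone X-ray MLV curves.
    - ``popc_chol20_saxs_mlv``: + 20 mol% cholesterol (merged CH2), with a
      smaller fluctuation parameter than its parent.
    - ``popc_sans_ulv`` / ``popc_d31_sans_ulv``: neutron contrast pair in
      pure D2O, differing only in the chain deuteration spec.
    - ``popc_joint``: SAXS MLV plus both neutron ULV curves sharing one
      bilayer (joint-refinement scenario).
    """
    lib: dict[str, TruthSpec] = {}

    dppc, dppc_scheme = _dppc_sdp()
    lib["dppc_saxs_mlv"] = TruthSpec(
        sdp=dppc,
        scheme=dppc_scheme,
        datasets=[
            DatasetSpec(
                name="dppc_saxs_mlv",
                geometry="mlv",
                contrast=Contrast(radiation="xray"),
                lattice=LatticeParams(d=67.0, N=20, eta=0.08, N_diff=1.0),
                **_SAXS_GRID,
            )
        ],
    )

    popc, popc_scheme = _popc_sdp()
    popc_lat = LatticeParams(d=64.0, N=20, eta=0.06, N_diff=1.0)
    lib["popc_saxs_mlv"] = TruthSpec(
        sdp=popc,
        scheme=popc_scheme,
        datasets=[
            DatasetSpec(
                name="popc_saxs_mlv",
                geometry="mlv",
                contrast=Contrast(radiation="xray"),
                lattice=popc_lat,
                **_SAXS_GRID,
            )
        ],
    )

    chol, chol_scheme = _popc_chol_sdp()
    lib["popc_chol20_saxs_mlv"] = TruthSpec(
        sdp=chol,
        scheme=chol_scheme,
        datasets=[
            DatasetSpec(
                name="popc_chol20_saxs_mlv",
                geometry="mlv",
                contrast=Contrast(radiation="xray"),
                lattice=LatticeParams(d=68.0, N=20, eta=0.05, N_diff=1.0),
                **_SAXS_GRID,
            )
        ],
    )

    d2o = dict(radiation="neutron", solvent_d2o_fraction=1.0)
    lib["popc_sans_ulv"] = TruthSpec(
        sdp=popc,
        scheme=popc_scheme,
        datasets=[
            DatasetSpec(
                name="popc_sans_ulv",
                geometry="ulv",
                contrast=Contrast(**d2o),
                **_SANS_GRID,
            )
        ],
    )
    lib["popc_d31_sans_ulv"] = TruthSpec(
        sdp=popc,
        scheme=popc_scheme,
        datasets=[
            DatasetSpec(
                name="popc_d31_sans_ulv",
                geometry="ulv",
                contrast=Contrast(deuteration=dict(_D31), **d2o),
                **_SANS_GRID,
            )
        ],
    )

    lib["popc_joint"] = TruthSpec(
        sdp=popc,
        scheme=popc_scheme,
        datasets=[
            DatasetSpec(
                name="popc_saxs_mlv",
                geometry="mlv",
                contrast=Contrast(radiation="xray"),
                lattice=popc_lat,
                **_SAXS_GRID,
            ),
            DatasetSpec(
                name="popc_sans_ulv",
                geometry="ulv",
                contrast=Contrast(**d2o),
                **_SANS_GRID,
            ),
            DatasetSpec(
                name="popc_d31_sans_ulv",
                geometry="ulv",
                contrast=Contrast(deuteration=dict(_D31), **d2o),
                **_SANS_GRID,
            ),
        ],
    )
    return lib
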