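"""Data readers, YAML run configuration, and result reports.

Scattering curves are plain whitespace-delimited ASCII columns
(q [1/A], I [arb.], sigma_I), the de-facto small-angle ``.dat`` convention;
'#' starts a comment.  A run is described by a YAML file holding the
parsing-scheme definition, the dataset list with contrast tags, fixed
inputs (lipid volume, cholesterol content) and the fit settings.  Reports
are a machine-readable JSON file plus CSV exports of the fitted profiles
and model-versus-data curves.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .fitting import Dataset, FitConfig, FitProblem, FitResult, PenaltyWeights
from .sdp import (
    BilayerSDP,
    Component,
    Contrast,
    ParsingScheme,
    default_pc_scheme,
    electron_density_profile,
    volume_profiles,
    water_profile,
)

__all__ = ["RunConfig", "read_curve", "load_config", "dump_config", "write_report"]

log = logging.getLogger("sdpgap")


# ---------------------------------------------------------------------------
# Curve reader
# ---------------------------------------------------------------------------


def read_curve(path, q_unit: str = "1/A") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a 2- or 3-column ASCII scattering curve.

    Returns (q, I, sigma).  '#' comment lines are skipped; rows with q <= 0
    are dropped with a warning.  A missing third column is synthesised as
    sigma = max(0.02 I, sqrt(I)) and logged.  ``q_unit`` may be "1/A" or
    "1/nm" (divided by 10 on read).
    """
    path = pathlib.Path(path)
    q, I, s = [], [], []
    have_sigma = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            try:
                vals = [float(x) for x in fields[:3]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from None
            if have_sigma is None:
                have_sigma = len(fields) >= 3
            q.append(vals[0])
            I.append(vals[1])
            s.append(vals[2] if len(vals) >= 3 else np.nan)
    q = np.asarray(q)
    I = np.asarray(I)
    s = np.asarray(s)
    if q_unit == "1/nm":
        q = q / 10.0
    elif q_unit != "1/A":
        raise ValueError(f"unknown q unit {q_unit!r}")
    keep = q > 0
    if not keep.all():
        log.warning("%s: dropped %d rows with q <= 0", path, int((~keep).sum()))
        q, I, s = q[keep], I[keep], s[keep]
    if not have_sigma:
        s = np.maximum(0.02 * np.abs(I), np.sqrt(np.clip(I, 0.0, None)))
        log.warning("%s: no sigma column; synthesised as max(0.02 I, sqrt(I))", path)
    if q.size < 20:
        raise ValueError(f"{path}: only {q.size} valid rows (need >= 20)")
    return q, I, s


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to run one fit: scheme, datasets, fixed inputs,
    fit settings and output directory."""

    scheme: ParsingScheme
    dataset_entries: list[dict]
    V_L: float
    fit: FitConfig = field(default_factory=FitConfig)
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    output_dir: str = "results"
    q_unit: str = "1/A"
    label: str = ""


def _scheme_from_dict(d: dict) -> ParsingScheme:
    if "preset" in d:
        return default_pc_scheme(
            n_CH2=d.get("n_CH2", 28),
            n_CH=d.get("n_CH", 0),
            n_CH3=d.get("n_CH3", 2),
            cholesterol_fraction=d.get("cholesterol_fraction", 0.0),
            volume_tolerance=d.get("volume_tolerance", 0.05),
        )
    comps = tuple(
        Component(
            name=c["name"],
            composition={k: float(v) for k, v in c["composition"].items()},
            volume_ref=float(c["volume_ref"]),
            role=c.get("role", "headgroup"),
            volume_tolerance=float(c.get("volume_tolerance", 0.05)),
        )
        for c in d["components"]
    )
    return ParsingScheme(
        components=comps,
        headgroup_volume_target=float(d.get("headgroup_volume_target", 331.0)),
        cholesterol_fraction=float(d.get("cholesterol_fraction", 0.0)),
        cholesterol_volume=float(d.get("cholesterol_volume", 630.0)),
    ).normalized()


def _scheme_to_dict(s: ParsingScheme) -> dict:
    return {
        "components": [
            {
                "name": c.name,
                "composition": dict(c.composition),
                "volume_ref": c.volume_ref,
                "role": c.role,
                "volume_tolerance": c.volume_tolerance,
            }
            for c in s.components
        ],
        "headgroup_volume_target": s.headgroup_volume_target,
        "cholesterol_fraction": s.cholesterol_fraction,
        "cholesterol_volume": s.cholesterol_volume,
    }


def load_config(path) -> RunConfig:
    path = pathlib.Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fit_kw = dict(raw.get("fit", {}))
    weights = fit_kw.pop("weights", None)
    fit_cfg = FitConfig(**fit_kw)
    if weights:
        fit_cfg.weights = PenaltyWeights(**weights)
    entries = raw.get("datasets", [])
    base = path.parent
    for e in entries:
        if "path" in e:
            p = pathlib.Path(e["path"])
            e["path"] = str(p if p.is_absolute() else base / p)
            if not pathlib.Path(e["path"]).exists():
                raise FileNotFoundError(f"dataset file not found: {e['path']}")
    return RunConfig(
        scheme=_scheme_from_dict(raw["scheme"]),
        dataset_entries=entries,
        V_L=float(raw["V_L"]),
        fit=fit_cfg,
        bounds={k: tuple(v) for k, v in raw.get("bounds", {}).items()},
        fixed=dict(raw.get("fixed", {})),
        output_dir=raw.get("output_dir", "results"),
        q_unit=raw.get("q_unit", "1/A"),
        label=raw.get("label", ""),
    )


def dump_config(cfg: RunConfig, path) -> None:
    raw = {
        "label": cfg.label,
        "scheme": _scheme_to_dict(cfg.scheme),
        "datasets": cfg.dataset_entries,
        "V_L": cfg.V_L,
        "fit": {
            k: v
            for k, v in asdict(cfg.fit).items()
            if k != "weights"
        },
        "bounds": {k: list(v) for k, v in cfg.bounds.items()},
        "fixed": cfg.fixed,
        "output_dir": cfg.output_dir,
        "q_unit": cfg.q_unit,
    }
    raw["fit"]["weights"] = asdict(cfg.fit.weights)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def datasets_from_config(cfg: RunConfig) -> list[Dataset]:
    """Load and tag every dataset entry of a run configuration."""
    out = []
    for i, e in enumerate(cfg.dataset_entries):
        q, I, s = read_curve(e["path"], q_unit=cfg.q_unit)
        contrast = Contrast(
            radiation=e.get("radiation", "xray"),
            solvent_d2o_fraction=float(e.get("solvent_d2o_fraction", 0.0)),
            deuteration={k: float(v) for k, v in e.get("deuteration", {}).items()},
        )
        out.append(
            Dataset(
                q=q,
                I=I,
                sigma=s,
                geometry=e.get("geometry", "mlv"),
                contrast=contrast,
                name=e.get("name", f"dataset{i}"),
                beam_sigma=float(e.get("beam_sigma", 0.0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(
    result: FitResult,
    problem: FitProblem,
    out_dir,
    config_echo: dict | None = None,
    dz: float = 0.1,
) -> pathlib.Path:
    """Write the JSON report plus CSV profile and model-curve exports.

    Returns the path of the JSON report.  The profile CSV carries z, the
    per-component volume probabilities, water, and the electron-density and
    neutron-SLD profiles; each model CSV carries q, I_obs, sigma, I_model.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sdp, scheme = result.sdp, problem.scheme

    report = {
        "params": result.params,
        "chi2_red": result.chi2_red,
        "chi2_red_per_dataset": dict(
            zip([ds.name for ds in problem.datasets], result.chi2_red_per_dataset)
        ),
        "structure": result.structure.as_dict() if result.structure else None,
        "spread": result.spread,
        "generations": result.generations,
        "seed": result.seed,
        "config": config_echo or {},
    }
    for key, val in list(report["params"].items()):
        if not np.isfinite(val):
            raise ValueError(f"non-finite value in report: {key}")
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    span = max(sdp.z_PCN + 15.0, sdp.D_C + 15.0)
    n = int(np.ceil(span / dz))
    z = np.linspace(-n * dz, n * dz, 2 * n + 1)
    profiles = volume_profiles(sdp, scheme, z)
    pw = water_profile(profiles)
    ed = electron_density_profile(sdp, scheme, z, Contrast(radiation="xray"))
    nsld = electron_density_profile(
        sdp, scheme, z, Contrast(radiation="neutron", solvent_d2o_fraction=1.0)
    )
    names = list(profiles)
    header = ",".join(["z"] + [f"P_{n}" for n in names] + ["P_W", "rho_e", "sld_n"])
    table = np.column_stack([z] + [profiles[n] for n in names] + [pw, ed, nsld])
    np.savetxt(out / "profiles.csv", table, delimiter=",", header=header, comments="")

    x_best = np.array(
        [result.params[s.name] for s in problem.free], dtype=float
    )
    curves = problem.model_curves(x_best)
    for ds, model in zip(problem.datasets, curves):
        tab = np.column_stack([ds.q, ds.I, ds.sigma, model])
        np.savetxt(
            out / f"fit_curve_{ds.name}.csv",
            tab,
            delimiter=",",
            header="q,I_obs,sigma,I_model",
            comments="",
        )
    log.info("report written to %s", report_path)
    return report_path
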