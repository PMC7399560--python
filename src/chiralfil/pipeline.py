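"""End-to-end orchestration: configuration, seed fan-out, staged runs.

A :class:`RunConfig` (plain nested dict, YAML-serializable) drives the
stages generate | import | spectra | twistwrithe | kernel | pitch |
binodal | pmf.  Each stage derives an independent random stream from the
single global seed via ``numpy.random.SeedSequence(seed).spawn``, keyed
by a fixed stage index, so stages can be rerun in isolation and still
reproduce the chained run bit for bit.  Every artifact is written next
to a serialized copy of the configuration that produced it.

Units policy: nm internally; tabular outputs use turns/um for twist,
1/mm for writhe, um for pitch, and g/L for concentrations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from . import interactions as itx
from . import spectra as spc
from . import synth
from . import twistwrithe as twr
from . import virial as vir

log = logging.getLogger("chiralfil.pipeline")

STAGE_INDEX = {"generate": 0, "import": 1, "spectra": 2, "twistwrithe": 3,
               "kernel": 4, "pitch": 5, "binodal": 6, "pmf": 7}

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "chiralfil_run",
    "design_label": "s",
    "chain": {
        "contour_length": 420.0,
        "segment_length": 0.34,
        "persistence_ratio": 8.0,     # l_p / l_c
        "axial_twist_turns": 0.0,     # total turns over the contour
    },
    "geometry": {
        "hex_radius": 2.6,
        "duplex_radius": 1.0,
        "rise": 0.34,
        "bp_per_turn": 10.5,
        "diameter": 6.0,
    },
    "linking": {
        "design_overtwist": 0.0,
        "partition_rule": "thermal",
        "writhe_coupling": 0.25,
        "solenoid_amplitude": 5.0,
        "amplitude_sd": 0.0,
    },
    "ensemble": {"n": 100},
    "analysis": {"trim_bp": 10, "smooth_window": 15, "smooth_order": 9,
                 "writhe_presmooth_window": 21},
    "interaction": {"site_diameter": 0.7, "site_charge": 0.5,
                    "c_salt": 0.26, "temperature": 293.0},
    "coarse_grain": {"mode": "duplex", "target_spacing": 2.0,
                     "bead_diameter": 2.2},
    "virial": {"n_bins": 16, "kernel_budget": 2_000_000,
               "elastic_budget": 8_000_000, "n_nodes": 48,
               "rho_scale": 1.3},
    "binodal": {"rho_lo_scale": 0.8, "rho_hi_scale": 2.5, "n_scan": 40},
    "pmf": {"gamma_max": 90.0, "n_gamma": 19, "budget": 1_000_000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def stage_seed(cfg: dict, stage: str) -> int:
    """Independent 31-bit seed for one stage from the global seed."""
    ss = np.random.SeedSequence(int(cfg["seed"]))
    children = ss.spawn(len(STAGE_INDEX))
    return int(children[STAGE_INDEX[stage]].generate_state(1)[0] % 2 ** 31)


def _outdir(cfg: dict) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _save_config(cfg: dict, out: Path, stage: str) -> None:
    with open(out / f"config_{stage}.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def chain_parameters(cfg: dict) -> synth.ChainParameters:
    c = cfg["chain"]
    lc = float(c["contour_length"])
    return synth.ChainParameters(
        contour_length=lc,
        segment_length=float(c["segment_length"]),
        persistence_length=float(c["persistence_ratio"]) * lc,
        axial_twist_rate=float(c["axial_twist_turns"]) / lc * 1e3,
        seed=int(cfg["seed"]))


def bundle_geometry(cfg: dict) -> synth.BundleGeometry:
    g = cfg["geometry"]
    lc = float(cfg["chain"]["contour_length"])
    return synth.BundleGeometry(
        hex_radius=float(g["hex_radius"]),
        duplex_radius=float(g["duplex_radius"]),
        rise=float(g["rise"]), bp_per_turn=float(g["bp_per_turn"]),
        bp_count=int(round(lc / float(g["rise"]))),
        diameter=float(g["diameter"]))


def linking_target(cfg: dict) -> synth.LinkingTarget:
    k = cfg["linking"]
    return synth.LinkingTarget(
        design_overtwist=float(k["design_overtwist"]),
        partition_rule=str(k["partition_rule"]),
        writhe_coupling=float(k["writhe_coupling"]),
        solenoid_amplitude=float(k["solenoid_amplitude"]),
        amplitude_sd=float(k["amplitude_sd"]))


def interaction_model(cfg: dict) -> itx.InteractionModel:
    m = cfg["interaction"]
    return itx.InteractionModel(
        site_diameter=float(m["site_diameter"]),
        site_charge=float(m["site_charge"]),
        c_salt=float(m["c_salt"]),
        temperature=float(m["temperature"]))


def ensemble_path(cfg: dict) -> Path:
    return _outdir(cfg) / "ensemble.h5"


def run_generate(cfg: dict) -> fio.ConformationEnsemble:
    out = _outdir(cfg)
    t0 = time.time()
    ens = synth.generate_ensemble(
        chain_parameters(cfg), bundle_geometry(cfg), linking_target(cfg),
        int(cfg["ensemble"]["n"]), stage_seed(cfg, "generate"),
        str(cfg["design_label"]))
    fio.write_ensemble(ens, ensemble_path(cfg))
    _save_config(cfg, out, "generate")
    log.info("generate: %d conformations in %.1f s", ens.count,
             time.time() - t0)
    return ens


def run_import(cfg: dict, topology, configuration, duplex_map=None
               ) -> fio.ConformationEnsemble:
    out = _outdir(cfg)
    ens = fio.read_oxdna(topology, configuration, duplex_map,
                         design_label=str(cfg["design_label"]))
    fio.write_ensemble(ens, ensemble_path(cfg))
    _save_config(cfg, out, "import")
    log.info("import: %d frames", ens.count)
    return ens


def _load_ensemble(cfg: dict) -> fio.ConformationEnsemble:
    path = ensemble_path(cfg)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the 'generate' or 'import' stage first")
    return fio.read_ensemble(path)


def run_spectra(cfg: dict, ens=None) -> pd.DataFrame:
    out = _outdir(cfg)
    ens = ens or _load_ensemble(cfg)
    a = cfg["analysis"]
    es = spc.ensemble_helicity(ens, int(a["trim_bp"]),
                               int(a["smooth_window"]),
                               int(a["smooth_order"]))
    lc = ens[0].contour_length
    lp = float(cfg["chain"]["persistence_ratio"]) * lc
    ref = spc.wlc_reference_spectrum(es.wavenumbers, lp, lc)
    df = pd.DataFrame({
        "k_per_nm": es.wavenumbers, "power_nm4": es.power,
        "power_se": es.power_se, "H_mean": es.H_mean, "H_se": es.H_se,
        "H_smooth": (es.H_smooth if es.H_smooth is not None
                     else np.full_like(es.H_mean, np.nan)),
        "wlc_reference_nm4": ref})
    df.to_csv(out / "spectra.tsv", sep="\t", index=False)
    _save_config(cfg, out, "spectra")
    return df


def run_twistwrithe(cfg: dict, ens=None) -> dict:
    out = _outdir(cfg)
    ens = ens or _load_ensemble(cfg)
    a = cfg["analysis"]
    res = twr.ensemble_twist_writhe(
        ens, int(a["trim_bp"]),
        presmooth_window=int(a["writhe_presmooth_window"]))
    link = linking_target(cfg)
    table = pd.DataFrame([{
        "design": str(cfg["design_label"]),
        "dTw_initial_turns_per_um": link.design_overtwist,
        "dTw_mean_turns_per_um": res.delta_tw_mean,
        "dTw_se": res.delta_tw_se,
        "Wr_mean_per_mm": res.writhe_mean,
        "Wr_se": res.writhe_se,
        "tw_wr_correlation": res.twist_writhe_correlation,
        "n_writhe_failures": res.n_writhe_failures,
    }])
    table.to_csv(out / "twist_writhe.tsv", sep="\t", index=False)
    _save_config(cfg, out, "twistwrithe")
    return table.iloc[0].to_dict()


def _bodies(cfg: dict, ens) -> itx.BodyEnsemble:
    cg = cfg["coarse_grain"]
    return itx.coarse_grain_ensemble(
        ens, interaction_model(cfg), str(cg["mode"]),
        float(cg["target_spacing"]), float(cg["bead_diameter"]))


def _reference_density(kernel: vir.VirialKernel, scale: float) -> float:
    """Density scale from the mean kernel: rho_scale x the Onsager-like
    transition estimate 4 / <v_excl>."""
    vex = -0.25 * float(np.mean(kernel.kappa))
    return scale * 4.0 / vex


def run_kernel(cfg: dict, ens=None):
    out = _outdir(cfg)
    ens = ens or _load_ensemble(cfg)
    bodies = _bodies(cfg, ens)
    v = cfg["virial"]
    kernel = vir.virial_kernel(bodies, interaction_model(cfg),
                               int(v["n_bins"]), int(v["kernel_budget"]),
                               stage_seed(cfg, "kernel"))
    np.savez(out / "kernel.npz", bin_centers=kernel.bin_centers,
             kappa=kernel.kappa, se=kernel.se)
    pd.DataFrame(kernel.kappa, index=kernel.bin_centers,
                 columns=kernel.bin_centers).to_csv(
        out / "kernel.tsv", sep="\t")
    _save_config(cfg, out, "kernel")
    return kernel, bodies


def run_pitch(cfg: dict, ens=None) -> dict:
    out = _outdir(cfg)
    ens = ens or _load_ensemble(cfg)
    bodies = _bodies(cfg, ens)
    model = interaction_model(cfg)
    v = cfg["virial"]
    kernel = vir.virial_kernel(bodies, model, int(v["n_bins"]),
                               int(v["kernel_budget"]),
                               stage_seed(cfg, "kernel"))
    rho = _reference_density(kernel, float(v["rho_scale"]))
    bp_count = bundle_geometry(cfg).bp_count * 6
    sol = vir.solve_cholesteric(
        bodies, model, rho, kernel,
        elastic_budget=int(v["elastic_budget"]),
        seed=stage_seed(cfg, "pitch"), n_nodes=int(v["n_nodes"]),
        bp_count=bp_count)
    report = {
        "rho_per_nm3": sol.rho, "concentration_gL": sol.concentration_gL,
        "order_parameter": sol.odf.order_parameter,
        "K2_kT_per_nm": sol.K2, "K2_se": sol.K2_se,
        "kt_kT_per_nm2": sol.kt, "kt_se": sol.kt_se,
        "pitch_um": sol.pitch_um, "pitch_se_um": sol.pitch_se_um,
        "achiral_within_error": sol.achiral_within_error,
    }
    with open(out / "pitch.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _save_config(cfg, out, "pitch")
    return report


def run_binodal(cfg: dict, ens=None) -> dict:
    out = _outdir(cfg)
    ens = ens or _load_ensemble(cfg)
    bodies = _bodies(cfg, ens)
    model = interaction_model(cfg)
    v = cfg["virial"]
    kernel = vir.virial_kernel(bodies, model, int(v["n_bins"]),
                               int(v["kernel_budget"]),
                               stage_seed(cfg, "kernel"))
    b = cfg["binodal"]
    rho0 = _reference_density(kernel, 1.0)
    pb = vir.binodal(kernel,
                     (rho0 * float(b["rho_lo_scale"]),
                      rho0 * float(b["rho_hi_scale"])),
                     n_nodes=int(v["n_nodes"]),
                     bp_count=bundle_geometry(cfg).bp_count * 6,
                     n_scan=int(b["n_scan"]))
    report = {"rho_iso_per_nm3": pb.rho_iso,
              "rho_chol_per_nm3": pb.rho_chol,
              "c_iso_gL": pb.c_iso_gL, "c_chol_gL": pb.c_chol_gL,
              "mu_residual": pb.mu_residual,
              "pressure_residual": pb.pressure_residual,
              "order_parameter": pb.order_parameter}
    pd.DataFrame([report]).to_csv(out / "binodal.tsv", sep="\t",
                                  index=False)
    with open(out / "binodal.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _save_config(cfg, out, "binodal")
    return report


def run_pmf(cfg: dict, ens=None) -> pd.DataFrame:
    out = _outdir(cfg)
    ens = ens or _load_ensemble(cfg)
    bodies = _bodies(cfg, ens)
    p = cfg["pmf"]
    gam = np.linspace(-float(p["gamma_max"]), float(p["gamma_max"]),
                      int(p["n_gamma"]))
    pmf = vir.chiral_pmf(bodies, interaction_model(cfg), gam,
                         int(p["budget"]), stage_seed(cfg, "pmf"))
    df = pd.DataFrame({"gamma_deg": pmf.gamma_deg, "W_kT": pmf.W,
                       "W_odd_kT": pmf.W_odd})
    df.attrs["gamma_star_deg"] = pmf.gamma_star_deg
    df.to_csv(out / "pmf.tsv", sep="\t", index=False)
    _save_config(cfg, out, "pmf")
    return df


def run_report(cfg: dict) -> dict:
    """Chain all stages on the configured ensemble and write report.json."""
    ens = run_generate(cfg)
    report = {"seed": int(cfg["seed"]),
              "design_label": str(cfg["design_label"]),
              "count": ens.count}
    spec_df = run_spectra(cfg, ens)
    i_low = 1 if len(spec_df) > 1 else 0
    report["H_low_k"] = float(spec_df["H_mean"].iloc[i_low])
    report["H_low_k_se"] = float(spec_df["H_se"].iloc[i_low])
    report.update(run_twistwrithe(cfg, ens))
    report.update(run_pitch(cfg, ens))
    out = _outdir(cfg)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
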