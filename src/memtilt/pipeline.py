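"""End-to-end analysis pipeline: stages chained into a report directory.

Given external data (structure + trajectory + selection expressions) the
pipeline runs tilt, contact and summary stages; without external data it runs
the built-in synthetic scenario presets end to end (the "demo"), which also
exercises the electrostatics and bilayer stages on generated fixtures.

Every output TSV carries '#' provenance headers (package version, seed,
stage parameters — no timestamps, so identical config + seed reproduces
byte-identical outputs).  A MANIFEST file lists the stages that completed;
on a stage failure the partial outputs and MANIFEST are retained.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocks import combine_runs, trailing_window_summary
from .config import AnalysisConfig
from .contacts import ContactConfig, contact_series
from .electrostatics import (charge_density_profile, integrate_potential,
                             potential_contrast)
from .io import read_structure, read_trajectory, write_trajectory, write_tsv
from .membrane import membrane_thickness, order_parameters
from .orientation import angle_distribution, tilt_series
from .select import select_atoms
from .synthetic import (BilayerFixtureSpec, ChargeFixtureSpec, PRESETS,
                        gen_bilayer, gen_charge_system, gen_dimer_trajectory,
                        preset_spec)

__all__ = ["run_analysis", "run_demo", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs were retained."""


def derive_seed(seed: int, index: int) -> int:
    """Stable per-task sub-seed below 2^31."""
    return (seed * 100003 + 7919 * index + 1) % (2**31)


def _meta(cfg: AnalysisConfig, stage: str, **extra) -> dict:
    meta = {"package": f"memtilt {__version__}", "stage": stage,
            "seed": cfg.seed}
    meta.update(extra)
    return meta


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: list[str] = []

    def done(self, stage: str) -> None:
        self.entries.append(stage)
        self.write()

    def write(self) -> None:
        (self.outdir / "MANIFEST").write_text(
            "".join(f"{e}\n" for e in self.entries))


def _tilt_component(series_vals: np.ndarray, absolute: bool) -> np.ndarray:
    return np.abs(series_vals) if absolute else series_vals


def _summarize_runs(runs: list[np.ndarray], window: float,
                    block_sizes) -> tuple[float, float]:
    per_run = [trailing_window_summary(r, window=window, block_sizes=block_sizes)
               for r in runs]
    combined = combine_runs([(s.mean, s.summary_ee) for s in per_run])
    return combined.mean, combined.ee


def run_demo(cfg: AnalysisConfig) -> Path:
    """Run the four synthetic scenario presets end to end.

    Per preset: generate the scheduled-tilt dimer fixture for each run, write
    tilt/contact series and the run-averaged angle histogram, and collect
    trailing-window mean ± EE summaries.  Two toy membranes (with/without
    the glycolipid, differing in chain order and sheet charge density) feed
    the thickness, order-parameter and potential stages.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    contact_cfg = ContactConfig(cutoff=cfg.cutoff)
    summary_rows = []
    for pi, name in enumerate(cfg.presets):
        preset = PRESETS[name]
        tilt_runs = {"overall": [], "lateral": [], "forward": []}
        contact_runs = []
        all_series = []
        for run in range(preset.n_runs):
            spec = preset_spec(name, n_frames=cfg.n_frames,
                               noise_deg=cfg.noise_deg,
                               seed=derive_seed(cfg.seed, 10 * pi + run))
            traj, truth, sels = gen_dimer_trajectory(spec)
            ts = tilt_series(traj, sels["proximal"], sels["distal"],
                             sels["monomer_a"], sels["monomer_b"],
                             label=f"{name}_run{run}")
            cs = contact_series(traj, sels["ecd_a"], sels["ecd_b"], contact_cfg)
            all_series.append(ts)
            for comp in tilt_runs:
                tilt_runs[comp].append(
                    _tilt_component(getattr(ts, comp), cfg.absolute_angles))
            contact_runs.append(cs.counts.astype(float))
            write_tsv(outdir / f"tilt_{name}_run{run}.tsv", pd.DataFrame({
                "time_ns": ts.times, "overall_deg": ts.overall,
                "lateral_deg": ts.lateral, "forward_deg": ts.forward,
            }), _meta(cfg, "tilt", preset=name, run=run))
            write_tsv(outdir / f"contacts_{name}_run{run}.tsv", pd.DataFrame({
                "time_ns": cs.times, "n_contacts": cs.counts,
            }), _meta(cfg, "contacts", preset=name, run=run,
                      cutoff_nm=cfg.cutoff,
                      selections=f"{cs.selection_a} | {cs.selection_b}"))
            write_tsv(outdir / f"truth_{name}_run{run}.tsv", truth,
                      _meta(cfg, "ground-truth", preset=name, run=run))
        hist = angle_distribution(all_series, component="overall",
                                  window=cfg.window, bin_width=cfg.bin_width)
        write_tsv(outdir / f"hist_overall_{name}.tsv", pd.DataFrame({
            "bin_left_deg": hist.edges[:-1], "bin_right_deg": hist.edges[1:],
            "density_per_deg": hist.density,
        }), _meta(cfg, "angle-distribution", preset=name,
                  window=cfg.window, bin_width_deg=cfg.bin_width,
                  n_runs=hist.n_runs))
        row = {"system": name, "label": preset.label, "n_runs": preset.n_runs,
               "scheduled_tilt_deg": preset.tilt_deg,
               "engineered_contacts": preset.contact_pairs}
        for comp in ("overall", "lateral", "forward"):
            m, e = _summarize_runs(tilt_runs[comp], cfg.window, cfg.block_sizes)
            row[f"{comp}_mean_deg"] = m
            row[f"{comp}_ee_deg"] = e
        m, e = _summarize_runs(contact_runs, cfg.window, cfg.block_sizes)
        row["contacts_mean"] = m
        row["contacts_ee"] = e
        summary_rows.append(row)
        manifest.done(f"preset:{name}")
    write_tsv(outdir / "summary.tsv", pd.DataFrame(summary_rows),
              _meta(cfg, "summary", window=cfg.window))
    manifest.done("summary")

    # membrane stages: two toy bilayers, the glycolipid-containing one more
    # ordered; thickness identical (4.8 nm plane separation) in both
    mem_rows = []
    for mi, (mem_name, kappa) in enumerate(
            (("glucer", 25.0), ("noglucer", 15.0))):
        spec = BilayerFixtureSpec(kappa=kappa,
                                  seed=derive_seed(cfg.seed, 100 + mi))
        traj, truth, extras = gen_bilayer(spec)
        thick = membrane_thickness(traj, extras["phosphates"])
        prof = order_parameters(traj, extras["chains"])
        write_tsv(outdir / f"order_{mem_name}.tsv", pd.DataFrame({
            "carbon_index": prof.positions, "s": prof.s,
        }), _meta(cfg, "order", membrane=mem_name, mode=prof.mode))
        mem_rows.append({
            "membrane": mem_name,
            "thickness_nm": float(thick.thickness.mean()),
            "s_mean": float(prof.s.mean()),
            "s_analytic": truth["s_analytic"],
        })
    manifest.done("membrane")

    # electrostatics: sheet systems with surface densities sigma and 1.3*sigma
    psis = {}
    for mem_name, sigma in (("glucer", 1.3), ("noglucer", 1.0)):
        cspec = ChargeFixtureSpec(sheets=[(-0.5, sigma), (0.5, -sigma)])
        traj, analytic = gen_charge_system(cspec, n_bins=cfg.n_bins)
        dens = charge_density_profile(traj, n_bins=cfg.n_bins)
        pot = integrate_potential(dens)
        psis[mem_name] = pot
        write_tsv(outdir / f"density_{mem_name}.tsv", pd.DataFrame({
            "z_nm": dens.z, "rho_e_per_nm3": dens.rho,
        }), _meta(cfg, "charge-density", membrane=mem_name))
        write_tsv(outdir / f"potential_{mem_name}.tsv", pd.DataFrame({
            "z_nm": pot.z, "psi_V": pot.psi,
        }), _meta(cfg, "potential", membrane=mem_name))
    contrast = potential_contrast(psis["glucer"], psis["noglucer"],
                                  region=(1.0, 4.0))
    mem_table = pd.DataFrame(mem_rows)
    mem_table["psi_contrast_vs_noglucer"] = [contrast, 0.0]
    write_tsv(outdir / "membranes.tsv", mem_table,
              _meta(cfg, "membranes", contrast_region_nm="1.0..4.0"))
    manifest.done("electrostatics")
    _write_log(cfg, outdir)
    manifest.done("log")
    return outdir


def _write_log(cfg: AnalysisConfig, outdir: Path) -> None:
    lines = [f"memtilt {__version__}"]
    for key, val in sorted(vars(cfg).items()):
        if key == "outdir":  # path-independent so reruns compare byte-identical
            continue
        lines.append(f"{key} = {val!r}")
    (outdir / "run.log").write_text("".join(f"{l}\n" for l in lines))


def run_analysis(cfg: AnalysisConfig) -> Path:
    """Run the configured analysis; demo presets when no trajectory is given."""
    if cfg.trajectory is None:
        return run_demo(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    try:
        topo, _ = read_structure(cfg.structure)
        traj = read_trajectory(cfg.trajectory, topo)
        sels = {role: select_atoms(topo, expr)
                for role, expr in cfg.selections.items()}
        manifest.done("load")
        ts = tilt_series(traj, sels["proximal"], sels["distal"],
                         sels["monomer_a"], sels["monomer_b"])
        write_tsv(outdir / "tilt.tsv", pd.DataFrame({
            "time_ns": ts.times, "overall_deg": ts.overall,
            "lateral_deg": ts.lateral, "forward_deg": ts.forward,
        }), _meta(cfg, "tilt"))
        hist = angle_distribution([ts], component="overall",
                                  window=cfg.window, bin_width=cfg.bin_width)
        write_tsv(outdir / "hist_overall.tsv", pd.DataFrame({
            "bin_left_deg": hist.edges[:-1], "bin_right_deg": hist.edges[1:],
            "density_per_deg": hist.density,
        }), _meta(cfg, "angle-distribution"))
        manifest.done("tilt")
        rows = {}
        for comp in ("overall", "lateral", "forward"):
            stats = trailing_window_summary(getattr(ts, comp),
                                            window=cfg.window,
                                            block_sizes=cfg.block_sizes)
            rows[f"{comp}_mean_deg"] = stats.mean
            rows[f"{comp}_ee_deg"] = stats.summary_ee
        if "monomer_a" in sels and "monomer_b" in sels:
            cs = contact_series(traj, sels["monomer_a"], sels["monomer_b"],
                                ContactConfig(cutoff=cfg.cutoff))
            write_tsv(outdir / "contacts.tsv", pd.DataFrame({
                "time_ns": cs.times, "n_contacts": cs.counts,
            }), _meta(cfg, "contacts", cutoff_nm=cfg.cutoff))
            stats = trailing_window_summary(cs.counts.astype(float),
                                            window=cfg.window,
                                            block_sizes=cfg.block_sizes)
            rows["contacts_mean"] = stats.mean
            rows["contacts_ee"] = stats.summary_ee
            manifest.done("contacts")
        if "phosphates" in sels:
            thick = membrane_thickness(traj, sels["phosphates"])
            write_tsv(outdir / "thickness.tsv", pd.DataFrame({
                "time_ns": thick.times, "thickness_nm": thick.thickness,
            }), _meta(cfg, "thickness"))
            rows["thickness_nm"] = float(thick.thickness.mean())
            manifest.done("thickness")
        write_tsv(outdir / "summary.tsv", pd.DataFrame([rows]),
                  _meta(cfg, "summary", window=cfg.window))
        manifest.done("summary")
        _write_log(cfg, outdir)
        manifest.done("log")
    except Exception as exc:
        manifest.write()
        raise PipelineError(f"stage failed after {manifest.entries}: {exc}") from exc
    return outdir
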