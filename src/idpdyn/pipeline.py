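"""Config-driven workflows tying the stages together.

Two presets mirror the study design: an experiment-emulation workflow
(synthetic QENS spectra → per-q and global fits → radii, volume fractions,
crowding scaling) and a simulation-emulation workflow (synthetic Brownian
ensembles → MSD diffusion with finite-size and isotope corrections → cluster
statistics, R_g, EISF, viscosity).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, constants as C
from . import hydro, qens, synthetic, trajectory as tr
from .io import read_spectrum_csv, read_spectrum_h5, read_xyz

log = logging.getLogger("idpdyn.pipeline")

__all__ = ["PipelineConfig", "RunReport", "run_qens_workflow", "run_traj_workflow"]


@dataclass
class PipelineConfig:
    """Declarative description of a pipeline run."""

    workflow: str = "qens"            # "qens" | "trajectory"
    seed: int = 0
    outdir: str = "idpdyn_out"
    plots: bool = False
    hydro: dict = field(default_factory=dict)      # temperature, isotope, salt_molarity
    concentration: float = 50.0                    # mg/mL
    qens_options: dict = field(default_factory=dict)
    traj_options: dict = field(default_factory=dict)
    input_spectrum: str | None = None
    input_trajectories: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def context(self) -> hydro.HydroContext:
        return hydro.HydroContext(
            temperature=self.hydro.get("temperature", 298.0),
            isotope=self.hydro.get("isotope", "D2O"),
            salt_molarity=self.hydro.get("salt_molarity", 0.0),
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Stage-by-stage outcome of a workflow run; every number traces back to
    a stage table and the recorded config hash and seed."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)   # name → DataFrame
    failures: dict = field(default_factory=dict)

    def add_stage(self, name: str, params: dict, elapsed: float) -> None:
        entry = self.stages.setdefault(name, {})
        entry.update({"params": params, "wall_time_s": round(elapsed, 3)})

    def fail_stage(self, name: str, error: Exception) -> None:
        self.failures[name] = f"{type(error).__name__}: {error}"
        log.warning("stage %s failed: %s", name, error)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        summary = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "failures": self.failures,
            "tables": sorted(self.tables),
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        return path


def _stage(report: RunReport, name: str, params: dict):
    """Context manager logging wall time and catching stage failures."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s started (seed %s)", name, report.seed)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                report.add_stage(name, params, time.perf_counter() - self.t0)
                return False
            report.fail_stage(name, exc)
            return True  # stage failures do not abort later stages

    return _Ctx()


# ---------------------------------------------------------------------------
# QENS workflow
# ---------------------------------------------------------------------------

def run_qens_workflow(config: PipelineConfig) -> RunReport:
    """Spectrum → per-q + global fits → R_eff, R_g, volume fractions, and
    crowding-scaling comparison."""
    report = RunReport(config_hash=config.hash(), seed=config.seed,
                       version=__version__)
    ctx = config.context()
    opts = dict(config.qens_options)
    truth = None

    with _stage(report, "load_spectrum", {"input": config.input_spectrum}):
        if config.input_spectrum:
            p = Path(config.input_spectrum)
            spectrum = read_spectrum_h5(p) if p.suffix in (".h5", ".hdf5") \
                else read_spectrum_csv(p)
        else:
            truth_kw = opts.get("truth", {})
            truth = synthetic.SpectrumTruth(seed=config.seed, **truth_kw)
            spectrum = synthetic.generate_spectrum(truth)

    policy = qens.SolventPolicy(**opts.get("solvent_policy", {}))
    n_starts = opts.get("n_starts", 5)

    with _stage(report, "fit_global", {"solvent_policy": policy.mode}):
        gf = qens.fit_global(spectrum, policy, n_starts=n_starts, seed=config.seed)
        report.tables["global_fit"] = pd.DataFrame({
            "parameter": ["D", "D_int", "tau"],
            "value": [gf.D, gf.D_int, gf.tau],
            "uncertainty": [gf.D_err, gf.D_int_err, gf.tau_err],
            "units": ["A2/ns", "A2/ns", "ns"],
        })
        report.tables["global_eisf"] = pd.DataFrame({
            "q": spectrum.q_values, "A0": gf.A0_q, "beta": gf.beta_q,
        })
        report.stages.setdefault("metrics", {})["global"] = {
            "gof": gf.gof, "l1": gf.l1, "l2": gf.l2}

    with _stage(report, "fit_per_q", {"solvent_policy": policy.mode}):
        pq = qens.fit_per_q(spectrum, policy, n_starts=n_starts, seed=config.seed)
        report.tables["per_q_fit"] = pd.DataFrame({
            "q": pq.q_values, "gamma": pq.gamma, "gamma_err": pq.gamma_err,
            "Gamma_int": pq.Gamma_int, "A0": pq.A0, "A0_err": pq.A0_err,
            "beta": pq.beta, "gof": pq.gof, "l1": pq.l1, "l2": pq.l2,
        })
        d_perq = qens.extract_D_from_gamma(
            pq.q_values, pq.gamma, pq.gamma_err, pq.valid)
        report.stages.setdefault("fit_per_q", {}).update(
            {"D_per_q": d_perq.value, "D_per_q_err": d_perq.uncertainty})

    with _stage(report, "derived_radii", {"T": ctx.temperature, "isotope": ctx.isotope}):
        rows = []
        D = gf.D
        r_eff = hydro.stokes_einstein_radius(D, ctx)
        rg = hydro.nygaard_rg_inverse(r_eff, C.HST5_N_RESIDUES)
        phi = hydro.volume_fraction(config.concentration)
        rg_ref = opts.get("rg_reference", 13.8)
        rh_ref = hydro.nygaard_rh(rg_ref, C.HST5_N_RESIDUES)
        phi_h = hydro.hydrodynamic_volume_fraction(phi, rh_ref, rg_ref)
        rows.append(("D_apparent", D, "A2/ns"))
        rows.append(("R_eff", r_eff, "A"))
        rows.append(("R_g_inverted", rg, "A"))
        rows.append(("phi_dry", phi, "1"))
        rows.append(("phi_h", phi_h, "1"))
        rows.append(("D_scaled_phi_h",
                     hydro.crowding_scale(D, phi_h), "A2/ns"))
        report.tables["derived"] = pd.DataFrame(
            rows, columns=["quantity", "value", "units"])

    if truth is not None:
        report.stages["truth"] = {
            "D_apparent": truth.D_apparent, "D_int": truth.D_int,
            "tau": truth.tau}
    if config.plots:
        with _stage(report, "plots", {}):
            _plot_spectrum_fit(spectrum, gf, Path(config.outdir))
    return report


def _plot_spectrum_fit(spectrum, gf, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    iq = spectrum.q_values.size // 2
    fig, ax = plt.subplots()
    ax.semilogy(spectrum.omega_values, spectrum.intensity[iq], ".", ms=3,
                label=f"data q={spectrum.q_values[iq]:.2f}")
    ax.set_xlabel("energy transfer (μeV)")
    ax.set_ylabel("S(q, ω)")
    ax.legend()
    fig.savefig(outdir / "spectrum_fit.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Trajectory workflow
# ---------------------------------------------------------------------------

def run_traj_workflow(config: PipelineConfig) -> RunReport:
    """Trajectories → diffusion with corrections, cluster statistics, R_g,
    and EISF."""
    report = RunReport(config_hash=config.hash(), seed=config.seed,
                       version=__version__)
    ctx = config.context()
    opts = dict(config.traj_options)
    window = tuple(opts.get("window", (0.0, 4.6)))
    cutoffs = opts.get("cutoffs", (6.0, 7.0))

    trajs: list[tr.ChainEnsembleTrajectory] = []
    with _stage(report, "load_trajectories",
                {"inputs": list(config.input_trajectories)}):
        if config.input_trajectories:
            for p in config.input_trajectories:
                try:
                    trajs.append(read_xyz(p))
                except Exception as exc:
                    raise RuntimeError(
                        f"could not read trajectory file {p!r}: {exc}") from exc
        else:
            truth_kw = opts.get("truth", {})
            n_rep = opts.get("n_replicates", 3)
            for r in range(n_rep):
                t = synthetic.BrownianSystemTruth(
                    seed=config.seed * 1000 + r, **truth_kw)
                trajs.append(synthetic.generate_brownian_chains(t))
            report.stages["truth"] = {"D_t": trajs and t.D_t}

    unwrapped = []
    with _stage(report, "diffusion", {"window": list(window)}):
        if not trajs:
            raise RuntimeError("no trajectories loaded; skipping analysis")
        unwrapped = [tr.unwrap(t) for t in trajs]
        mean, singles = tr.ensemble_diffusion(unwrapped, window=window)
        L = float(trajs[0].box_at(0)[0])
        fsp = tr.FiniteSizeParams.cubic(
            L=L, eta=hydro.viscosity_water(ctx.temperature, "H2O"),
            T=ctx.temperature)
        corrected = tr.yeh_hummer_correct(mean, fsp)
        rescaled = tr.isotope_rescale(corrected, ctx.temperature)
        report.tables["diffusion"] = pd.DataFrame({
            "quantity": ["D_pbc", "D_finite_size", "D_isotope_rescaled"],
            "value": [mean.value, corrected.value, rescaled.value],
            "uncertainty": [mean.uncertainty, corrected.uncertainty,
                            rescaled.uncertainty],
            "r_squared": [mean.r_squared] * 3,
            "corrections": ["", "finite_size",
                            "finite_size+isotope_rescaled"],
        })
        report.tables["diffusion_per_chain"] = pd.DataFrame({
            "replicate": np.repeat(np.arange(len(unwrapped)),
                                   [t.chains.size for t in unwrapped]),
            "chain": np.concatenate([t.chains for t in unwrapped]),
            "D_t": [e.value for e in singles],
            "r_squared": [e.r_squared for e in singles],
        })

    with _stage(report, "clusters", {"cutoffs": list(cutoffs)}):
        rows = []
        for rep, t in enumerate(trajs):
            if t.chains.size < 2:
                continue
            stride = max(t.n_frames // opts.get("cluster_frames", 50), 1)
            for f in range(0, t.n_frames, stride):
                dmat = tr.min_chain_distance(t, f)
                for cut in cutoffs:
                    st = tr.cluster_chains(dmat, cutoff=cut)
                    rows.append((rep, f, cut, st.n_clusters,
                                 st.n_participating, st.largest))
        report.tables["clusters"] = pd.DataFrame(
            rows, columns=["replicate", "frame", "cutoff", "n_clusters",
                           "n_participating", "largest"])
        if rows:
            df = report.tables["clusters"]
            report.stages.setdefault("clusters", {})["summary"] = {
                f"cutoff_{cut:g}": {
                    "mean_n_clusters": float(df[df.cutoff == cut].n_clusters.mean()),
                    "mean_participating": float(
                        df[df.cutoff == cut].n_participating.mean()),
                    "mean_largest": float(df[df.cutoff == cut].largest.mean()),
                } for cut in cutoffs}

    with _stage(report, "rg", {}):
        rows = []
        for rep, t in enumerate(unwrapped):
            for chain in t.chains:
                rg = tr.rg_series(t, chain)
                rows.append((rep, chain, float(rg.mean()), float(rg.std())))
        report.tables["rg"] = pd.DataFrame(
            rows, columns=["replicate", "chain", "rg_mean", "rg_std"])

    eisf_opts = opts.get("eisf")
    if eisf_opts is not None:
        with _stage(report, "eisf", dict(eisf_opts)):
            fix = synthetic.generate_confined_hydrogens(
                n_atoms=eisf_opts.get("n_atoms", 64),
                a=eisf_opts.get("radius", 1.2),
                D_loc=eisf_opts.get("D_loc", 2.0),
                dt=eisf_opts.get("dt", 0.005),
                n_steps=eisf_opts.get("n_steps", 2000),
                seed=config.seed)
            qv = np.asarray(eisf_opts.get("q_values", [0.4, 0.8, 1.2, 1.6]))
            a0 = tr.eisf_from_trajectory(fix, qv, remove_com=False,
                                         seed=config.seed)
            report.tables["eisf"] = pd.DataFrame({"q": qv, "A0": a0})
    return report
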