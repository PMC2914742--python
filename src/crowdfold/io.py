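"""Configuration, serialisation and report generation.

The canonical tabular format is TSV (tab-separated, header row, '.'
decimal); plots are a convenience layer and never an input.  Config files
are YAML (JSON is valid YAML and accepted too).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from crowdfold.model import ProteinModel
from crowdfold.simulate import CrowdedSystemSpec
from crowdfold.spt import CrowderFluid, crowding_pmf

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "load_config",
    "write_config",
    "write_tsv",
    "write_xyz",
    "write_report",
]

log = logging.getLogger(__name__)

_GRID_KEYS = {"R_c", "phi", "c_urea"}
_SIM_KEYS = {
    "box_edge_angstrom",
    "reduced_box",
    "duration_tu",
    "relax_tu",
    "burn_in_fraction",
    "sample_interval",
    "q",
    "t_m",
    "n_seeds",
    "overlap_check_interval",
}
_TOP_KEYS = {"model", "grid", "simulation", "seed"}


@dataclass
class ExperimentConfig:
    """Validated experiment grid plus simulation settings."""

    model: ProteinModel
    R_c: list[float]
    phi: list[float]
    c_urea: list[float]
    seed: int = 0
    n_seeds: int = 4
    base_spec: CrowdedSystemSpec = None

    def to_dict(self) -> dict:
        s = self.base_spec
        return {
            "model": self.model.to_dict(),
            "grid": {
                "R_c": list(self.R_c),
                "phi": list(self.phi),
                "c_urea": list(self.c_urea),
            },
            "simulation": {
                "box_edge_angstrom": s.box,
                "reduced_box": s.reduced_box,
                "duration_tu": s.production_tu,
                "relax_tu": s.relax_tu,
                "burn_in_fraction": s.burn_in_fraction,
                "sample_interval": s.sample_interval,
                "q": s.q,
                "t_m": s.t_table,
                "n_seeds": self.n_seeds,
                "overlap_check_interval": s.overlap_check_interval,
            },
            "seed": self.seed,
        }

    @property
    def n_cells(self) -> int:
        return len(self.R_c) * len([p for p in self.phi if p > 0]) + 1


def _require(cond: bool, msg: str):
    if not cond:
        raise ValueError(msg)


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config; defaults are filled in.

    Raises
    ------
    ValueError
        On unknown keys, out-of-range volume fractions, non-increasing bin
        edges, or a missing/empty grid; messages name the offending key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(
            f"empty or malformed config {path}; required sections: "
            f"grid (with keys {sorted(_GRID_KEYS)}); optional: model, simulation, seed"
        )
    unknown = set(raw) - _TOP_KEYS
    _require(not unknown, f"unknown top-level config keys: {sorted(unknown)}")
    model = ProteinModel.from_dict(raw.get("model", {}))
    grid = raw.get("grid")
    _require(isinstance(grid, dict), "config must contain a 'grid' section")
    unknown = set(grid) - _GRID_KEYS
    _require(not unknown, f"unknown grid keys: {sorted(unknown)}")
    _require("c_urea" in grid, "grid.c_urea is required")
    c_urea = [float(c) for c in grid["c_urea"]]
    _require(all(c >= 0 for c in c_urea), "grid.c_urea entries must be >= 0")
    phi = [float(p) for p in grid.get("phi", [0.0])]
    for p in phi:
        _require(0.0 <= p <= 0.5, f"grid.phi entry {p} outside [0, 0.5]")
    R_c = [float(r) for r in grid.get("R_c", [1.0])]
    _require(all(r > 0 for r in R_c), "grid.R_c entries must be positive")
    sim = dict(raw.get("simulation", {}))
    unknown = set(sim) - _SIM_KEYS
    _require(not unknown, f"unknown simulation keys: {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    n_seeds = int(sim.pop("n_seeds", 4))
    _require(n_seeds >= 1, "simulation.n_seeds must be >= 1")
    base_spec = CrowdedSystemSpec(
        c_urea=c_urea[0],
        model=model,
        box=float(sim.get("box_edge_angstrom", 210.0)),
        reduced_box=bool(sim.get("reduced_box", False)),
        production_tu=float(sim.get("duration_tu", 10_000.0)),
        relax_tu=float(sim.get("relax_tu", 200.0)),
        burn_in_fraction=float(sim.get("burn_in_fraction", 0.1)),
        sample_interval=float(sim.get("sample_interval", 1.0)),
        q=float(sim.get("q", 0.2)),
        t_table=float(sim.get("t_m", 10.0)),
        overlap_check_interval=float(sim.get("overlap_check_interval", 100.0)),
    )
    return ExperimentConfig(
        model=model, R_c=R_c, phi=phi, c_urea=c_urea, seed=seed,
        n_seeds=n_seeds, base_spec=base_spec,
    )


def write_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


@dataclass
class RunManifest:
    """Inventory of one pipeline run: config snapshot, seeds, outputs."""

    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    cell_stats: list[dict] = field(default_factory=list)
    version: str = ""

    def __post_init__(self):
        if not self.version:
            from crowdfold import __version__

            self.version = __version__

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        payload = {
            "crowdfold_version": self.version,
            "python": platform.python_version(),
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs,
            "cell_stats": self.cell_stats,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_xyz(path, positions, kinds, box: float, comment: str = "") -> None:
    """Append one frame of wrapped coordinates in XYZ format."""
    names = np.where(np.asarray(kinds) == 0, "S", "C")
    wrapped = np.mod(positions, box)
    with open(path, "a") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for name, (x, y, z) in zip(names, wrapped):
            fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_report(results: dict, outdir, config: ExperimentConfig | None = None) -> list[Path]:
    """Write TSV tables and figures for a (possibly partial) grid run.

    ``results`` is the mapping returned by
    :func:`crowdfold.simulate.run_experiment_grid` (``curves`` and ``c50``
    DataFrames).  Produces denaturation-curve panels (theory vs DMD), a
    depletion-potential panel per crowder size, and a c50-versus-phi table
    and plot.  Gaps in partial grids are flagged in the log and left out of
    the plots.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    curves = results["curves"]
    c50 = results["c50"]
    if curves.empty:
        raise ValueError("no completed cells to report")
    for name, df in (("curves.tsv", curves), ("c50.tsv", c50)):
        p = outdir / name
        write_tsv(df, p)
        written.append(p)

    n_missing = int(curves["f_native"].isna().sum())
    if n_missing:
        log.warning("report contains %d missing grid points (left blank)", n_missing)

    # denaturation curves, one panel per (R_c, phi)
    cells = curves[["R_c", "phi"]].drop_duplicates().to_numpy()
    ncols = min(4, len(cells))
    nrows = (len(cells) + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows), squeeze=False, sharey=True
    )
    for ax, (rc, phi) in zip(axes.ravel(), cells):
        sel = (curves["phi"] == phi) & (
            curves["R_c"].isna() if np.isnan(rc) else curves["R_c"] == rc
        )
        for source, style in (("theory", "s--"), ("dmd", "o-")):
            sub = curves[sel & (curves["source"] == source)].dropna(subset=["f_native"])
            if len(sub):
                ax.errorbar(
                    sub["c_urea_M"], sub["f_native"], yerr=sub["stderr"],
                    fmt=style, ms=4, capsize=2, label=source,
                )
        title = "dilute" if phi == 0 else f"R_c={rc:g}, phi={phi:g}"
        ax.set(title=title, xlabel="c_urea [M]", ylabel="f_native", ylim=(-0.05, 1.05))
        ax.legend(fontsize=7)
    for ax in axes.ravel()[len(cells):]:
        ax.set_axis_off()
    fig.tight_layout()
    p = outdir / "denaturation_curves.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    if config is not None:
        # depletion PMF panels
        model = config.model
        fig, ax = plt.subplots(figsize=(5, 4))
        r = np.linspace(model.edges[0], model.edges[-1], 500)
        for rc in config.R_c:
            for phi in config.phi:
                if phi <= 0:
                    continue
                pmf = crowding_pmf(CrowderFluid.from_ratio(rc, phi, model.subunit_radius))
                ax.plot(r, pmf(r), label=f"R_c={rc:g}, phi={phi:g}", lw=1)
                df = pmf.to_frame(r)
                p = outdir / f"pmf_Rc{rc:g}_phi{phi:g}.tsv"
                write_tsv(df, p)
                written.append(p)
        ax.set(xlabel="r [A]", ylabel="U_crowd [kT]")
        if len(ax.lines):
            ax.legend(fontsize=6)
        fig.tight_layout()
        p = outdir / "u_crowd.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

    # c50 versus phi
    if len(c50):
        fig, ax = plt.subplots(figsize=(5, 4))
        for (rc, method), sub in c50.groupby(["R_c", "method"], dropna=False):
            sub = sub.sort_values("phi")
            marker = "o-" if method == "dmd" else "d--"
            lbl = f"R_c={rc:g} ({method})" if not np.isnan(rc) else f"dilute ({method})"
            ax.plot(sub["phi"], sub["c50_M"], marker, ms=5, label=lbl)
        ax.set(xlabel="phi", ylabel="c50 [M]")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / "c50_vs_phi.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
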