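"""End-to-end analysis pipeline: events → breaks → fragments → fits → report.

A :class:`RunConfig` (round-trippable through YAML) fixes every input and
every seed; :func:`run_pipeline` then produces delimited-text tables, an
optional set of figures regenerable from those tables alone, a
machine-readable ``summary.json`` and a run log.  Identical configs produce
byte-identical tables: all randomness derives from the master seed, and no
timestamps enter any table (the log records wall-clock time, the tables do
not).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .damage import (
    DamageParams,
    call_direct_threshold,
    call_direct_window,
    call_indirect,
    break_profile,
    dsb_yield,
    merge_breaks,
    ssb_yield,
)
from .fragments import (
    fragment_distribution,
    kandaiya_inverse,
    write_fragment_distribution,
)
from .fitting import (
    ExperimentalData,
    fit_poh,
    fit_threshold,
    read_experimental_data,
    residual_curve,
    yield_curves,
)
from .tracks import (
    GeneratorConfig,
    SOFT_EVENT_CUTOFF_EV,
    energy_histogram,
    generate_events,
    per_base_statistics,
    read_scored_events,
    write_scored_events,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("iodinedna")

FLOAT_FMT = "%.10g"  # fixed so identical configs yield byte-identical tables


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every stochastic stage's seed is
    derived from the master ``seed``.

    Either ``events_path`` (a scored-event file) or ``generator`` (with
    ``n_events``) supplies the dataset.  Fits run against the observed
    fragment tables when given, or against the dataset's own fragment
    distribution when ``self_fit`` is true; requesting fits with neither is
    a pre-flight error.
    """

    outdir: str = "run"
    seed: int = 1
    n_events: int = 20000
    events_path: str | None = None
    generator: GeneratorConfig | None = None
    damage: DamageParams = field(default_factory=lambda: DamageParams(e_thresh=29.5, p_oh=0.16))
    e_grid: tuple[float, float, float] = (10.0, 40.0, 0.25)  # start, stop, step
    p_grid: tuple[float, float, float] = (0.0, 1.0, 0.01)
    max_site: int = 30
    observed_high: str | None = None
    observed_low: str | None = None
    self_fit: bool = False
    run_fits: bool = True
    yield_grid_step: float = 0.5
    figures: bool = True

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "n_events": self.n_events,
            "events_path": self.events_path,
            "generator": self.generator.to_dict() if self.generator else None,
            "damage": {
                "e_thresh": self.damage.e_thresh,
                "window": list(self.damage.window) if self.damage.window else None,
                "p_oh": self.damage.p_oh,
                "dsb_max_sep": self.damage.dsb_max_sep,
                "seed": self.damage.seed,
            },
            "e_grid": list(self.e_grid),
            "p_grid": list(self.p_grid),
            "max_site": self.max_site,
            "observed_high": self.observed_high,
            "observed_low": self.observed_low,
            "self_fit": self.self_fit,
            "run_fits": self.run_fits,
            "yield_grid_step": self.yield_grid_step,
            "figures": self.figures,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        dmg = d.get("damage") or {}
        window = dmg.get("window")
        return cls(
            outdir=d.get("outdir", "run"),
            seed=int(d.get("seed", 1)),
            n_events=int(d.get("n_events", 20000)),
            events_path=d.get("events_path"),
            generator=GeneratorConfig.from_dict(d["generator"]) if d.get("generator") else None,
            damage=DamageParams(
                e_thresh=float(dmg.get("e_thresh", 29.5)),
                window=tuple(window) if window else None,
                p_oh=float(dmg.get("p_oh", 0.16)),
                dsb_max_sep=int(dmg.get("dsb_max_sep", 10)),
                seed=int(dmg.get("seed", 1)),
            ),
            e_grid=tuple(d.get("e_grid", (10.0, 40.0, 0.25))),
            p_grid=tuple(d.get("p_grid", (0.0, 1.0, 0.01))),
            max_site=int(d.get("max_site", 30)),
            observed_high=d.get("observed_high"),
            observed_low=d.get("observed_low"),
            self_fit=bool(d.get("self_fit", False)),
            run_fits=bool(d.get("run_fits", True)),
            yield_grid_step=float(d.get("yield_grid_step", 0.5)),
            figures=bool(d.get("figures", True)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration.  Placement-only keys
        (outdir, figures) are excluded so identical analyses hash equal
        regardless of where their artifacts land."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("figures", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _grid(spec: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = spec
    return np.round(np.arange(start, stop + 1e-9, step), 6)


def _preflight(config: RunConfig) -> None:
    """Fail on missing inputs before any computation."""
    if config.events_path is not None and not Path(config.events_path).exists():
        raise FileNotFoundError(f"events file not found: {config.events_path}")
    for p in (config.observed_high, config.observed_low):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"observed-data file not found: {p}")
    if config.run_fits and not (config.self_fit or config.observed_high):
        raise ValueError(
            "fits requested but no observed data given and self_fit is off; "
            "set observed_high/observed_low, enable self_fit, or set run_fits: false"
        )


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config: {cfg_hash}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artifacts under ``config.outdir``.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir, cfg_hash)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, cfg_hash: str) -> dict:
    log.info("iodinedna %s on python %s", __version__, platform.python_version())
    log.info("config hash %s, master seed %d", cfg_hash, config.seed)
    config.to_yaml(outdir / "config.yaml")

    # ---- dataset ----------------------------------------------------------
    if config.events_path:
        dataset = read_scored_events(config.events_path)
        log.info("read %d decays from %s", dataset.n_decays, config.events_path)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        if gen.seed != config.seed:
            gen = GeneratorConfig.from_dict({**gen.to_dict(), "seed": config.seed})
        dataset = generate_events(gen, config.n_events)
        log.info("generated %d decays (seed %d)", dataset.n_decays, gen.seed)
        write_scored_events(dataset, outdir / "events.csv")

    max_site = min(config.max_site, dataset.n_bases - 1)

    # ---- per-base statistics & energy histograms --------------------------
    stats = per_base_statistics(dataset)
    _write(stats.to_frame(), outdir / "per_base_stats.csv", cfg_hash)
    hist_i = energy_histogram(
        dataset, "per-interaction", bin_width=0.5, exclude_below=SOFT_EVENT_CUTOFF_EV
    )
    _write(hist_i.to_frame(), outdir / "energy_hist_per_interaction.csv", cfg_hash)
    base10 = min(10, dataset.n_bases - 1)
    hist_b = energy_histogram(
        dataset, "per-decay-per-base", base=base10, strand=0, bin_width=1.0,
        exclude_below=SOFT_EVENT_CUTOFF_EV,
    )
    _write(hist_b.to_frame(), outdir / f"energy_hist_base{base10}.csv", cfg_hash)

    # ---- break calls ------------------------------------------------------
    dmg = config.damage
    if dmg.window is not None:
        direct = call_direct_window(dataset, *dmg.window, seed=config.seed)
    else:
        direct = call_direct_threshold(dataset, dmg.e_thresh)
    calls = [direct]
    if dmg.p_oh > 0:
        calls.append(call_indirect(dataset, dmg.p_oh, seed=config.seed))
    merged = merge_breaks(calls)
    _write(merged.to_frame(), outdir / "breaks.csv", cfg_hash)

    ssb0 = ssb_yield(merged, 0)
    ssb1 = ssb_yield(merged, 1)
    dsb = dsb_yield(merged, dmg.dsb_max_sep)
    log.info("SSB/decay strand0 %.4f, strand1 %.4f, DSB/decay %.4f",
             ssb0.value, ssb1.value, dsb.value)

    # ---- fragment distributions and the inversion -------------------------
    frag_bo = fragment_distribution(merged, 0, max_site, "breaks_only")
    frag_iu = fragment_distribution(merged, 0, max_site, "include_unbroken")
    write_fragment_distribution(frag_bo, outdir / "fragments_breaks_only.csv")
    write_fragment_distribution(frag_iu, outdir / "fragments_include_unbroken.csv")

    profile = break_profile(merged, 0, max_site)
    corrected = kandaiya_inverse(frag_bo)
    recovered = kandaiya_inverse(frag_iu)
    inv = pd.DataFrame(
        {
            "site": np.arange(max_site + 1),
            "p_true": profile.p,
            "p_from_breaks_only": corrected.p,
            "p_from_include_unbroken": recovered.p,
        }
    )
    _write(inv, outdir / "inversion.csv", cfg_hash)
    occupied = np.nonzero(frag_bo.f > 0)[0]
    degeneracy_p = float(corrected.p[occupied[0]]) if occupied.size else float("nan")
    log.info("inversion on breaks_only data assigns p=%.6f at innermost occupied site",
             degeneracy_p)

    # ---- fits -------------------------------------------------------------
    summary_fits: dict = {}
    if config.run_fits:
        e_grid = _grid(config.e_grid)
        p_grid = _grid(config.p_grid)
        if config.observed_high:
            obs_high = read_experimental_data(config.observed_high, "high")
        else:  # self-fit: the direct-only fragment distribution is the "observation"
            fd = fragment_distribution(direct, 0, max_site, "breaks_only")
            obs_high = ExperimentalData(fd, "high")
        fit_e = fit_threshold(dataset, obs_high, e_grid)
        _write(residual_curve(fit_e), outdir / "sse_curve_threshold.csv", cfg_hash)
        log.info("best e_thresh %.3f ± %.3f eV (SSE %.4g, %d bins excluded)",
                 fit_e.best, fit_e.uncertainty, fit_e.sse[fit_e.best_index],
                 fit_e.n_bins_excluded)
        summary_fits["e_thresh_eV"] = {
            "best": fit_e.best,
            "uncertainty": fit_e.uncertainty,
            "sse": float(fit_e.sse[fit_e.best_index]),
            "bins_excluded": fit_e.n_bins_excluded,
            "within_2x_min": [float(v) for v in fit_e.values_within(2.0)],
        }

        obs_low = None
        if config.observed_low:
            obs_low = read_experimental_data(config.observed_low, "low")
        elif config.self_fit and dmg.p_oh > 0:
            fd = fragment_distribution(merged, 0, max_site, "breaks_only")
            obs_low = ExperimentalData(fd, "low")
        if obs_low is not None:
            fit_p = fit_poh(dataset, obs_low, fit_e.best, p_grid, seed=config.seed)
            _write(residual_curve(fit_p), outdir / "sse_curve_poh.csv", cfg_hash)
            log.info("best p_oh %.3f ± %.3f (SSE %.4g)", fit_p.best,
                     fit_p.uncertainty, fit_p.sse[fit_p.best_index])
            summary_fits["p_oh"] = {
                "best": fit_p.best,
                "uncertainty": fit_p.uncertainty,
                "sse": float(fit_p.sse[fit_p.best_index]),
                "bins_excluded": fit_p.n_bins_excluded,
                "within_2x_min": [float(v) for v in fit_p.values_within(2.0)],
            }

    # ---- yield curves -----------------------------------------------------
    ygrid = _grid((config.e_grid[0], config.e_grid[1], config.yield_grid_step))
    ycurves = yield_curves(dataset, ygrid, dmg.dsb_max_sep)
    _write(ycurves, outdir / "yield_curves.csv", cfg_hash)

    # ---- summary ----------------------------------------------------------
    summary = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "package_version": __version__,
        "n_decays": dataset.n_decays,
        "n_bases": dataset.n_bases,
        "label": dataset.label,
        "max_site": max_site,
        "damage": {
            "e_thresh": dmg.e_thresh,
            "window": list(dmg.window) if dmg.window else None,
            "p_oh": dmg.p_oh,
            "dsb_max_sep": dmg.dsb_max_sep,
        },
        "yields": {
            "ssb_per_decay_strand0": [ssb0.value, ssb0.se],
            "ssb_per_decay_strand1": [ssb1.value, ssb1.se],
            "dsb_per_decay": [dsb.value, dsb.se],
        },
        "inversion_innermost_p_breaks_only": degeneracy_p,
        "fits": summary_fits,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.figures:
        _figures(outdir, stats, hist_i, frag_bo, inv, summary_fits, ycurves, cfg_hash)
    return summary


def _figures(outdir, stats, hist_i, frag_bo, inv, fits, ycurves, cfg_hash) -> None:
    """Plots regenerated purely from the exported tables' contents."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    fig, ax = plt.subplots(1, 2, figsize=(9, 3.5))
    nb = stats.mean_energy_per_decay.shape[1]
    ax[0].semilogy(range(nb), np.maximum(stats.mean_energy_per_decay[0], 1e-6), "o-", ms=3)
    ax[0].set(xlabel="base (0 = iodine)", ylabel="mean energy / decay (eV)",
              title="Energy deposited per base, strand 0")
    ax[1].semilogy(range(nb), np.maximum(stats.mean_oh_hits[0], 1e-6), "s-", ms=3, color="C2")
    ax[1].set(xlabel="base (0 = iodine)", ylabel="OH hits / decay",
              title="OH interactions per base, strand 0")
    fig.tight_layout()
    fig.savefig(figdir / "per_base_stats.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    centers = 0.5 * (hist_i.edges[:-1] + hist_i.edges[1:])
    ax.bar(centers, hist_i.counts, width=np.diff(hist_i.edges), color="C0")
    ax.set(xlabel="energy per interaction (eV)", ylabel="interactions", yscale="log",
           title="Interaction energy spectrum")
    fig.tight_layout()
    fig.savefig(figdir / "energy_hist_per_interaction.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.semilogy(frag_bo.sites, np.maximum(frag_bo.f, 1e-6), "o-", ms=3)
    ax.set(xlabel="break site (most distant break)", ylabel="fragment fraction",
           title="Fragment-size distribution (breaks only)")
    fig.tight_layout()
    fig.savefig(figdir / "fragment_distribution.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.plot(inv["site"], inv["p_true"], "o-", ms=3, label="true per-site probability")
    ax.plot(inv["site"], inv["p_from_breaks_only"], "s--", ms=3,
            label="inverted from breaks-only fractions")
    ax.plot(inv["site"], inv["p_from_include_unbroken"], "^:", ms=3,
            label="inverted with unbroken fraction")
    ax.set(xlabel="base", ylabel="break probability / decay",
           title="Inversion degeneracy of normalised fragment data")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(figdir / "inversion_degeneracy.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.plot(ycurves["e_thresh_eV"], ycurves["ssb_per_decay"], "-", label="SSB strand 0")
    ax.plot(ycurves["e_thresh_eV"], ycurves["dsb_per_decay"], "-", label="DSB")
    ax.set(xlabel="energy threshold (eV)", ylabel="breaks / decay",
           title="Yield vs threshold")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "yield_curves.png", dpi=120)
    plt.close(fig)
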