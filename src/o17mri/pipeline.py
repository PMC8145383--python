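"""End-to-end orchestration: synthetic cohort -> fits -> group statistics.

A single :class:`RunConfig` (YAML-loadable) describes the acquisition
protocol, the cohort groups, the noise level and the grid of model cells
(model x alpha x Tc) to fit — mirroring the model-comparison design of an
inhalation study.  :func:`run_experiment` produces per-subject fits for
every cell, group summaries, between-group Mann-Whitney tests per cell,
and a Friedman + Dunn comparison of models within the reference group.
Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import fit_linear, fit_three_phase, fit_washout
from .protocol import AcquisitionProtocol, GroupSpec, KineticParams, NoiseSpec
from .stats import dunn_posthoc, friedman_test, mann_whitney_exact, pearson_corr
from .synthetic import Subject, cohort_to_frame, make_group_dataset

__all__ = ["ModelSpec", "RunConfig", "RunResult", "run_experiment", "render_report"]

#: Tc value used to represent the "immediate availability" limit Tc -> 0.
TC_NEAR_ZERO = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """One quantification cell: model name, enrichment fraction, delay."""

    name: str  # "linear" | "three_phase"
    alpha: float
    tc_s: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("linear", "three_phase"):
            raise ValueError(f"unknown model {self.name!r}")

    @property
    def label(self) -> str:
        if self.name == "linear":
            return f"linear_a{self.alpha:g}"
        return f"3phase_a{self.alpha:g}_tc{self.tc_s:g}"


@dataclass
class RunConfig:
    protocol: AcquisitionProtocol
    groups: list[GroupSpec]
    noise: NoiseSpec
    models: list[ModelSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.models) == 0:
            raise ValueError("at least one model cell is required")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        prot = d.get("protocol", {})
        protocol = AcquisitionProtocol(
            t_baseline=prot.get("t_baseline_s", 300.0),
            t_inhale=prot.get("t_inhale_s", 200.0),
            t_washout=prot.get("t_washout_s", 900.0),
            frame_dt=prot.get("frame_dt_s", 18.2),
            alpha=prot.get("alpha", 0.7),
            tc=prot.get("tc_s", 0.0),
        )
        groups = [
            GroupSpec(
                label=g["label"],
                n_subjects=int(g["n_subjects"]),
                params_mean=KineticParams(**g["mean"]),
                params_sd=KineticParams(**g.get("sd", dict(cmro2=0, k_g=0, k_l=0))),
            )
            for g in d["groups"]
        ]
        noise_d = d.get("noise", {})
        seed = int(d["seed"])
        noise = NoiseSpec(
            sigma=noise_d.get("sigma", 0.5),
            distribution=noise_d.get("distribution", "gaussian"),
            seed=seed,
        )
        models = [
            ModelSpec(name=m["name"], alpha=m["alpha"], tc_s=m.get("tc_s", 0.0))
            for m in d["models"]
        ]
        return cls(protocol=protocol, groups=groups, noise=noise, models=models, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def paper_preset(cls, seed: int = 0) -> "RunConfig":
        """The shipped default study design (two groups of 4, full model grid)."""
        text = resources.files("o17mri").joinpath("presets/paper.yaml").read_text()
        d = yaml.safe_load(text)
        d["seed"] = seed
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "protocol": {
                "t_baseline_s": self.protocol.t_baseline,
                "t_inhale_s": self.protocol.t_inhale,
                "t_washout_s": self.protocol.t_washout,
                "frame_dt_s": self.protocol.frame_dt,
                "alpha": self.protocol.alpha,
                "tc_s": self.protocol.tc,
            },
            "groups": [
                {
                    "label": g.label,
                    "n_subjects": g.n_subjects,
                    "mean": asdict(g.params_mean),
                    "sd": asdict(g.params_sd),
                }
                for g in self.groups
            ],
            "noise": {"sigma": self.noise.sigma, "distribution": self.noise.distribution},
            "models": [
                {"name": m.name, "alpha": m.alpha, "tc_s": m.tc_s} for m in self.models
            ],
            "seed": self.seed,
        }


@dataclass
class RunResult:
    config: RunConfig
    cohort: list[Subject]
    fits: pd.DataFrame  # one row per subject x model cell
    washout: pd.DataFrame  # one row per subject
    group_summary: pd.DataFrame
    stats: dict


def _fit_cell(subject: Subject, model: ModelSpec, protocol: AcquisitionProtocol) -> dict:
    row = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "model": model.label,
        "alpha": model.alpha,
        "tc_s": model.tc_s,
        "k_g": np.nan,
        "k_l": np.nan,
    }
    if model.name == "linear":
        res = fit_linear(subject.curve, alpha=model.alpha, protocol=protocol)
        row.update(cmro2=res.cmro2, cmro2_se=res.cmro2_se)
    else:
        res = fit_three_phase(
            subject.curve, alpha=model.alpha, tc=model.tc_s, protocol=protocol
        )
        row.update(
            cmro2=res.params.cmro2,
            cmro2_se=res.se["cmro2"],
            k_g=res.params.k_g,
            k_l=res.params.k_l,
        )
    return row


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Run the full synthetic experiment described by ``config``.

    Per-subject fits for every model cell, per-subject washout fits,
    group means +/- SE per cell, Mann-Whitney between the first two groups
    per cell, and Friedman + Dunn across cells within the first group.
    If ``outdir`` is given, all tables plus a manifest are written there.
    """
    protocol = config.protocol
    cohort = make_group_dataset(config.groups, protocol, config.noise, seed=config.seed)

    fit_rows = [
        _fit_cell(sub, model, protocol) for sub in cohort for model in config.models
    ]
    fits = pd.DataFrame(fit_rows)

    washout_rows = []
    for sub in cohort:
        wres = fit_washout(sub.curve, protocol)
        washout_rows.append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                "k_washout": wres.k_washout,
                "k2": wres.k2,
                "degenerate": wres.degenerate,
            }
        )
    washout = pd.DataFrame(washout_rows)

    group_summary = (
        fits.groupby(["model", "group"])["cmro2"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    group_summary["se"] = group_summary["sd"] / np.sqrt(group_summary["n"])

    stats: dict = {"per_cell_mann_whitney": {}, "seed": config.seed}
    labels = [g.label for g in config.groups]
    if len(labels) >= 2:
        g1, g2 = labels[0], labels[1]
        for model in config.models:
            cell = fits[fits["model"] == model.label]
            x = cell[cell["group"] == g1]["cmro2"].to_numpy()
            y = cell[cell["group"] == g2]["cmro2"].to_numpy()
            if len(x) and len(y):
                mw = mann_whitney_exact(x, y)
                stats["per_cell_mann_whitney"][model.label] = {
                    "U": mw.statistic,
                    "p": mw.p_two_sided,
                    "exact": mw.exact,
                }
        xw = washout[washout["group"] == g1]["k_washout"].dropna().to_numpy()
        yw = washout[washout["group"] == g2]["k_washout"].dropna().to_numpy()
        if len(xw) and len(yw):
            mww = mann_whitney_exact(xw, yw)
            stats["k_washout_mann_whitney"] = {"U": mww.statistic, "p": mww.p_two_sided}

    # model-comparison within the reference (first) group
    ref = labels[0]
    ref_fits = fits[fits["group"] == ref]
    cell_labels = [m.label for m in config.models]
    wide = ref_fits.pivot(index="subject_id", columns="model", values="cmro2")[cell_labels]
    if wide.shape[0] >= 2 and wide.shape[1] >= 2 and wide.notna().all().all():
        fr = friedman_test(wide.to_numpy())
        stats["friedman_reference_group"] = {
            "chi2": fr.statistic,
            "p": fr.p_two_sided,
            "exact": fr.exact,
        }
        comparisons = [(0, j) for j in range(1, len(cell_labels))]
        dunn = dunn_posthoc(wide.to_numpy(), comparisons=comparisons, labels=cell_labels)
        stats["dunn_vs_first_cell"] = {
            f"{a} vs {b}": {"z": r.statistic, "p_adjusted": r.p_two_sided}
            for (a, b), r in dunn.items()
        }

    # CMRO2 (first cell) vs the CBF index across all subjects
    first_cell = fits[fits["model"] == cell_labels[0]].set_index("subject_id")["cmro2"]
    merged = washout.set_index("subject_id").join(first_cell, how="inner").dropna(
        subset=["cmro2", "k_washout"]
    )
    if len(merged) >= 3 and merged["cmro2"].std() > 0 and merged["k_washout"].std() > 0:
        pc = pearson_corr(merged["cmro2"].to_numpy(), merged["k_washout"].to_numpy())
        stats["cmro2_vs_k_washout_pearson"] = {"r": pc.statistic, "p": pc.p_two_sided}

    result = RunResult(
        config=config,
        cohort=cohort,
        fits=fits,
        washout=washout,
        group_summary=group_summary,
        stats=stats,
    )
    if outdir is not None:
        _write_run(result, Path(outdir))
    return result


def _write_run(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(result.cohort).to_csv(outdir / "cohort.csv", index=False)
    result.fits.to_csv(outdir / "fits.csv", index=False)
    result.washout.to_csv(outdir / "washout.csv", index=False)
    result.group_summary.to_csv(outdir / "group_summary.csv", index=False)
    (outdir / "stats.json").write_text(json.dumps(result.stats, indent=2, default=float))
    config_json = json.dumps(result.config.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": result.config.seed,
        "o17mri_version": __version__,
        "n_frames": result.config.protocol.n_frames,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "config.yaml").write_text(yaml.safe_dump(result.config.to_dict()))


def render_report(result: RunResult, outdir: str | Path) -> list[Path]:
    """Plots + CSV of the numbers shown: group time-courses and per-cell boxes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    protocol = result.config.protocol

    # group mean +/- SD time-course with inhalation-window markers
    fig, ax = plt.subplots(figsize=(7, 4))
    frame = cohort_to_frame(result.cohort)
    plotted = []
    for label, sub in frame.groupby("group", sort=False):
        wide = sub.pivot(index="t_s", columns="subject_id", values="conc_umol_per_g")
        mean = wide.mean(axis=1)
        ax.plot(mean.index / 60.0, mean, label=label)
        if wide.shape[1] > 1:
            sd = wide.std(axis=1)
            ax.fill_between(mean.index / 60.0, mean - sd, mean + sd, alpha=0.25)
            plotted.append(
                pd.DataFrame(
                    {"group": label, "t_s": mean.index, "mean": mean.values, "sd": sd.values}
                )
            )
        else:
            plotted.append(
                pd.DataFrame(
                    {"group": label, "t_s": mean.index, "mean": mean.values, "sd": 0.0}
                )
            )
    ax.axvline(protocol.t_baseline / 60.0, color="grey", ls=":")
    ax.axvline((protocol.t_baseline + protocol.t_inhale) / 60.0, color="grey", ls=":")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("excess H$_2^{17}$O (umol/g)")
    ax.legend()
    fig.tight_layout()
    tc_png = outdir / "timecourses.png"
    fig.savefig(tc_png, dpi=120)
    plt.close(fig)
    written.append(tc_png)

    pd.concat(plotted, ignore_index=True).to_csv(outdir / "timecourses.csv", index=False)
    written.append(outdir / "timecourses.csv")

    # per-cell CMRO2 boxes
    fig, ax = plt.subplots(figsize=(8, 4))
    cells = [m.label for m in result.config.models]
    groups = [g.label for g in result.config.groups]
    data, positions, colors = [], [], []
    for ci, cell in enumerate(cells):
        for gi, g in enumerate(groups):
            vals = result.fits.query("model == @cell and group == @g")["cmro2"]
            data.append(vals.to_numpy())
            positions.append(ci * (len(groups) + 1) + gi)
            colors.append(f"C{gi}")
    bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True, whis=(0, 100))
    for patch, color in zip(bp["boxes"], colors):
        patch.set_facecolor(color)
    ax.set_xticks([ci * (len(groups) + 1) + (len(groups) - 1) / 2 for ci in range(len(cells))])
    ax.set_xticklabels(cells, rotation=30, ha="right")
    ax.set_ylabel("CMRO$_2$ (umol/g/min)")
    fig.tight_layout()
    box_png = outdir / "model_comparison.png"
    fig.savefig(box_png, dpi=120)
    plt.close(fig)
    written.append(box_png)

    result.fits.round(6).to_csv(outdir / "report_fits.csv", index=False)
    written.append(outdir / "report_fits.csv")
    return written
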