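#!/usr/bin/env python
"""Figures: 6S per perturbation type, peri-perturbation step series,
divergence curves.  Reads the tables written by steps 02-04 and writes
PNGs to ``results/figures/``."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"
FIG = ROOT / "figures"

LABEL_ORDER = ["PD", "NPD", "1D", "2ND", "3D", "4ND", "5D", "6ND"]


def plot_six_s():
    six = pd.read_csv(ROOT / "six_s.tsv", sep="\t")
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=False)
    for ax, param, title in zip(axes, ("mos_ml", "mos_ap"), ("6S ML MoS", "6S AP MoS")):
        sub = six[six["parameter"] == param].sort_values("six_s", ascending=False)
        ax.bar(sub["ptype"], sub["six_s"], color="0.4")
        ax.set_title(title)
        ax.set_ylabel("6S (m)")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(FIG / "six_s.png", dpi=120)


def plot_peri_steps():
    peri = pd.read_csv(ROOT / "peri_steps.tsv", sep="\t")
    params = ["mos_ap", "mos_ml", "step_length", "step_width", "step_time"]
    for ptype in peri["ptype"].unique():
        sub = peri[peri["ptype"] == ptype]
        fig, axes = plt.subplots(len(params), 1, figsize=(6, 10), sharex=True)
        for ax, param in zip(axes, params):
            cell = sub[sub["parameter"] == param].set_index("label").reindex(LABEL_ORDER)
            ax.errorbar(LABEL_ORDER, cell["mean"], yerr=cell["sd"], fmt="o-", color="k", ms=4)
            ax.set_ylabel(param)
            ax.axvline(1.5, color="0.7", ls="--")  # trigger between NPD and 1D
        axes[-1].set_xlabel("step")
        fig.suptitle(ptype)
        fig.tight_layout()
        fig.savefig(FIG / f"peri_{ptype}.png", dpi=120)
        plt.close(fig)


def plot_divergence():
    curves = pd.read_csv(ROOT / "lds_curves.tsv", sep="\t")
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5), sharey=True)
    for ax, axis in zip(axes, ("ML", "AP", "VT")):
        for trial, sub in curves[curves["axis"] == axis].groupby("trial"):
            ax.plot(sub["dt"] / 100.0, sub["mean_log_divergence"], label=trial)
        ax.set_title(axis)
        ax.set_xlabel("strides")
    axes[0].set_ylabel("mean ln divergence")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(FIG / "divergence_curves.png", dpi=120)


def main():
    FIG.mkdir(parents=True, exist_ok=True)
    plot_six_s()
    plot_peri_steps()
    plot_divergence()
    print(f"wrote figures to {FIG}")


if __name__ == "__main__":
    main()
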