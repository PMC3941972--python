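"""Figure-style plots: per-family log fold ratios, per-site
coverage/heterogeneity panels, and the terminal-branch-length histogram."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_enrichment(report: pd.DataFrame, path) -> None:
    """Log10 fold ratio per family, one bar per repeat family."""
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(report)), 3.5))
    ratios = report["fold_ratio"].replace([np.inf, -np.inf], np.nan)
    ax.bar(report["family_id"], np.log10(ratios))
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("log10 fold ratio")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_site_profiles(profiles_by_strain: dict, path) -> None:
    """Two-row panel per strain: coverage/million and major-variant
    frequency along the consensus."""
    strains = sorted(profiles_by_strain)
    fig, axes = plt.subplots(2, len(strains), figsize=(5 * len(strains), 5),
                             squeeze=False, sharex=True)
    for j, strain in enumerate(strains):
        prof = profiles_by_strain[strain]
        x = np.arange(prof.length)
        cov = (prof.coverage_per_million() if prof.mapped_denominator
               else prof.depth)
        axes[0][j].plot(x, cov, lw=0.7)
        axes[0][j].set_title(strain)
        axes[0][j].set_ylabel("coverage / 1e6 mapped")
        axes[1][j].plot(x, prof.major_fraction(), ".", ms=1.5)
        axes[1][j].set_ylim(0.2, 1.05)
        axes[1][j].set_ylabel("major-variant freq")
        axes[1][j].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_age_histogram(branch_lengths, path, bins: int = 30) -> None:
    """Terminal branch length distribution (substitutions/bp)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(branch_lengths, bins=bins)
    ax.set_xlabel("terminal branch length (subs/bp)")
    ax.set_ylabel("fragments")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
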