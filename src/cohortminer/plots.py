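"""Optional scatter plots of the conditional-prevalence analysis.

One figure per (condition, direction): each dot is a term at (marginal LOR,
normalised conditional LOR); the green curve is the per-bin mean, the red
curve the one-sided 95% upper bound; terms flagged in both directions are
blue, terms flagged in one direction orange. Plots are artifacts only —
nothing downstream reads them.

Requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

from pathlib import Path

from .reporting import RunManifest
from .synergy import DIRECTIONS, bin_and_flag, conditional_profile, synergistic_terms


def plot_direction(records, summaries, path: Path, both_flagged: set[str], title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    xs = [r.x for r in records]
    ys = [r.y_norm for r in records]
    colors = [
        "tab:blue" if r.term_id in both_flagged else ("tab:orange" if r.flagged else "0.6")
        for r in records
    ]
    ax.scatter(xs, ys, s=8, c=colors, alpha=0.7, linewidths=0)
    mids = [(s.x_low + s.x_high) / 2 for s in summaries]
    ax.plot(mids, [s.mean for s in summaries], color="green", label="bin mean")
    ax.plot(mids, [s.upper for s in summaries], color="red", label="95% one-sided bound")
    ax.set_xlabel("marginal prevalence LOR (vs. background)")
    ax.set_ylabel("normalised conditional prevalence")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_run(manifest: RunManifest, outdir: Path) -> list[Path]:
    """Write the scatter for each direction of the target condition."""
    family = manifest.load_family()
    cid = manifest.target_condition
    per_direction = {}
    for direction in DIRECTIONS:
        records, _ = conditional_profile(
            family, cid, direction, epsilon=manifest.epsilon_x,
            normalization=manifest.normalization,  # type: ignore[arg-type]
        )
        summaries = bin_and_flag(
            records, n_bins=manifest.n_bins, z=manifest.z,
            min_bin_count=manifest.min_bin_count,
        )
        per_direction[direction] = (records, summaries)
    report = synergistic_terms(
        (r.term_id for r in per_direction["index_given_condition"][0] if r.flagged),
        (r.term_id for r in per_direction["condition_given_index"][0] if r.flagged),
        cid,
    )
    written = []
    for direction, (records, summaries) in per_direction.items():
        path = outdir / f"scatter_{cid}_{direction}.png"
        plot_direction(records, summaries, path, set(report.synergistic), f"{cid}: {direction}")
        written.append(path)
    return written
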