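#!/usr/bin/env python
"""Per-subject normalized feature profiles across the configuration grid.

For one subject, each feature's 12 values are divided by their maximum
over the grid (so the maximum maps to 1), making the relative variation
across dynamic ranges and spatial resolutions directly visible. Writes
results/profiles_subject0.csv and a four-panel figure
(Entropy, Homogeneity, SRE, LRE) under scratch/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from tumortex import normalized_feature_profiles

ROOT = Path(__file__).resolve().parents[1]
PANELS = ["Entropy", "Homogeneity", "SRE", "LRE"]


def main() -> None:
    features = pd.read_csv(ROOT / "results" / "features.csv")
    subject = features[features["subject"] == 0]
    prof = normalized_feature_profiles(subject)
    out_csv = ROOT / "results" / "profiles_subject0.csv"
    prof.to_csv(out_csv, index=False, float_format="%.6g")
    print(f"wrote {out_csv}")

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, feat in zip(axes.ravel(), PANELS):
        for (m, st), block in prof.groupby(["matrix_size", "slice_thickness_mm"]):
            block = block.sort_values("n_levels")
            ax.plot(block["n_levels"], block[feat], marker="o",
                    label=f"{m}x{m}, {st:g} mm")
        ax.set_title(feat)
        ax.set_ylim(0, 1.05)
        ax.set_xscale("log", base=2)
        ax.set_xticks([16, 32, 64], ["16", "32", "64"])
    for ax in axes[1]:
        ax.set_xlabel("grey levels (dynamic range)")
    for ax in axes[:, 0]:
        ax.set_ylabel("feature / max over grid")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle("Subject 0: normalized texture features across the configuration grid")
    fig.tight_layout()
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_dir / "profiles_subject0.png", dpi=150)
    print(f"wrote {fig_dir / 'profiles_subject0.png'}")


if __name__ == "__main__":
    main()
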