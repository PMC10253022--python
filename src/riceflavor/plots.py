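"""Optional figures.

Only one figure type is produced: the per-sample flavor spectrogram as a
bar chart — bar position is the compound's retention time, bar height its
average intensity (AI), and the identification frequency (FQ) is annotated
above each bar.  Venn region sizes are reported as TSV/JSON by
:mod:`riceflavor.commonality` rather than drawn.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .olfactometry import Spectrogram


def plot_spectrogram(spec: Spectrogram, path: str | Path) -> None:
    """Save a flavor-spectrogram bar chart for one sample."""
    det = spec.entries[spec.entries["FQ"] >= 1]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(det["retention_time"], det["AI"], width=0.25, color="#3b6ea5")
    for row in det.itertuples(index=False):
        ax.annotate(str(int(row.FQ)), (row.retention_time, row.AI),
                    ha="center", va="bottom", fontsize=7)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("average intensity (AI)")
    ax.set_ylim(0, 5.5)
    ax.set_title(f"Flavor spectrogram — {spec.sample_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
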