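"""Minimal figures: a LOD curve and a delta-PVE profile."""

from __future__ import annotations

from .scan import ScanResult
from .varcomp import VarCompProfile


def plot_lod(res: ScanResult, which: str = "lod_nei", ax=None):
    """LOD curve along the genome, chromosomes laid side by side."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = res.table
    offset = 0.0
    for chrom, sub in t.groupby("chromosome", sort=False):
        x = sub["position"].to_numpy() + offset
        ax.plot(x, sub[which], label=str(chrom))
        obs = sub["is_marker"].to_numpy()
        ax.plot(x[obs], sub[which].to_numpy()[obs], "o", ms=3, color=ax.lines[-1].get_color())
        offset = x.max() + 5
    ax.set_xlabel("position (cM, chromosomes concatenated)")
    ax.set_ylabel(which.replace("_", " "))
    return ax


def plot_delta_pve(profile: VarCompProfile, ax=None):
    """PVE_nei (or RVE_nei) against spatial scale, selected scale marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    t = profile.table
    ax.plot(t["s"], t["pve_nei"], "o-")
    ax.axvline(profile.s_hat, ls="--", color="gray")
    ax.set_xlabel("spatial scale s")
    ax.set_ylabel("PVE_nei" if profile.family == "gaussian" else "RVE_nei")
    return ax
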