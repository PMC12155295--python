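"""Minimal profile plots (matplotlib, no styling opinions)."""

from __future__ import annotations

import numpy as np

from .indices import IndexProfile


def plot_profile(profile: IndexProfile, ax=None, show_samples: bool = True):
    """Per-stage index line with optional jittered per-sample points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    stages = list(profile.per_stage.index)
    x = np.arange(len(stages))
    ax.plot(x, profile.per_stage.to_numpy(), "o-", color="C0", label="stage index")
    if show_samples:
        rng = np.random.default_rng(0)  # jitter only, cosmetic
        for i, stage in enumerate(stages):
            samples = profile.stages.index[profile.stages == stage]
            vals = profile.per_sample.loc[samples]
            ax.scatter(
                np.full(len(vals), i) + rng.uniform(-0.12, 0.12, len(vals)),
                vals,
                s=12,
                alpha=0.5,
                color="C1",
            )
    ax.set_xticks(x, stages)
    ax.set_xlabel("stage")
    ax.set_ylabel(profile.index_kind)
    ax.set_title(f"{profile.index_kind} profile ({profile.aggregation})")
    return ax


def plot_stage_boxes(profile: IndexProfile, ax=None):
    """Boxplot of per-sample index values by stage."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    stages = list(profile.per_stage.index)
    data = [
        profile.per_sample.loc[profile.stages.index[profile.stages == s]].to_numpy()
        for s in stages
    ]
    ax.boxplot(data, tick_labels=stages)
    ax.set_xlabel("stage")
    ax.set_ylabel(profile.index_kind)
    return ax
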