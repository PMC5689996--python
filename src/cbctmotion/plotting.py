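"""Profile plotting helpers (matplotlib)."""

from __future__ import annotations

from .profile import CTProfile


def plot_profiles(profiles: list[CTProfile], labels: list[str] | None = None,
                  ax=None, step: bool = True):
    """Plot one or more profiles as HU-vs-position curves.

    Returns the matplotlib axes.  Profiles are drawn as steps (one level per
    imaging window) by default.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if labels is None:
        labels = [p.metadata.get("kind", f"profile {i}") for i, p in enumerate(profiles)]
    for profile, label in zip(profiles, labels):
        if step:
            ax.step(profile.positions, profile.values, where="mid", label=label)
        else:
            ax.plot(profile.positions, profile.values, label=label)
    ax.set_xlabel("position along superior–inferior axis (mm)")
    ax.set_ylabel("CT number above background (HU)")
    ax.legend()
    return ax
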