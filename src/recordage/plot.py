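"""Basic figure export for record-age densities and mean-age curves."""

from __future__ import annotations


def plot_density_series(distributions, ax=None, labels=None):
    """Overlay record-age densities for several evaluation years."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for i, dist in enumerate(distributions):
        label = labels[i] if labels else f"{dist.t:.0f}"
        ax.plot(dist.ages, dist.density, label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("density (1/year)")
    ax.set_xlim(dist.ages[0], dist.ages[-1])
    ax.legend(title="year", fontsize="small")
    return ax


def plot_mean_age(summary, ax=None, observed=None):
    """Mean record age with a one-sd band; optionally overlay data.

    ``summary`` is a frame with columns year/mean/sd (as produced by
    ``TitleholderResults.predict_mean_age``); ``observed`` an optional
    (times, ages) pair.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(summary["year"], summary["mean"], color="green", label="model mean")
    ax.plot(summary["year"], summary["mean"] + summary["sd"], "--", color="green", lw=0.8)
    ax.plot(summary["year"], summary["mean"] - summary["sd"], "--", color="green", lw=0.8)
    if observed is not None:
        ax.plot(observed[0], observed[1], color="C0", lw=0.8, label="observed")
    ax.set_xlabel("year")
    ax.set_ylabel("record age (years)")
    ax.legend(fontsize="small")
    return ax
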