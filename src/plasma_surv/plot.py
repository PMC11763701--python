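"""Minimal Kaplan-Meier plotting for risk-group evaluation."""

from __future__ import annotations


def plot_km_groups(km_curves: dict, ax=None, title: str | None = None):
    """Step plot of per-group Kaplan-Meier curves.

    ``km_curves`` maps group label -> :class:`~plasma_surv.survival.KMCurve`
    (as produced by the prediction evaluation).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"low": "tab:green", "high": "tab:red"}
    for label, curve in km_curves.items():
        ax.step(
            curve.times, curve.survival, where="post",
            label=f"{label} risk", color=colors.get(label),
        )
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
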