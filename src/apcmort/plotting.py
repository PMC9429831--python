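"""Basic diagnostic plots: effect curves and rate-series comparison."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .apc_core import EffectEstimates


def plot_effects(estimates: EffectEstimates, path) -> None:
    """Three-panel age/period/cohort effect curves on the log-rate scale."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    panels = (
        ("Age effect", estimates.ages, estimates.age_effects),
        ("Period effect", estimates.periods, estimates.period_effects),
        ("Cohort effect", estimates.cohorts, estimates.cohort_effects),
    )
    for ax, (title, x, y) in zip(axes, panels):
        ax.plot(x, y, marker=".", lw=1)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(title)
        ax.set_xlabel("year")
    axes[0].set_ylabel("effect (log rate)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rate_comparison(series_list, path) -> None:
    """Overlay crude / age-adjusted / age-cohort adjusted rate series."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series_list:
        label = s.kind + (f" ({s.link_variant})" if s.link_variant else "")
        ax.plot(s.years, s.rates, marker=".", label=label)
    ax.set_xlabel("calendar year")
    ax.set_ylabel(f"rate per {int(series_list[0].rate_scale):,}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
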