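"""Figure helpers: fit overlays with shaded response lobes, survey frames."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_fit_overlay", "plot_survey_frame"]


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_fit_overlay(waveform, fit, metrics=None, path=None):
    """Waveform with its double-gamma fit; positive/negative lobes shaded."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 3.2))
    t0 = fit.t0
    t = waveform.times - t0
    y = (waveform.values - 1.0) * 100.0
    ax.plot(t, y, color="tab:blue", lw=1.2, label="waveform")
    if fit.params is not None:
        tt = np.linspace(max(t.min(), 0.0), t.max(), 600)
        yy = fit.predict(tt)
        ax.plot(tt, yy, "r--", lw=1.4,
                label=f"double-gamma fit (R$^2$={fit.r_squared:.3f})")
        if metrics is not None:
            lo, hi = metrics.positive_interval
            sel = (tt >= lo) & (tt <= hi)
            ax.fill_between(tt[sel], 0, np.clip(yy[sel], 0, None),
                            color="red", alpha=0.25)
            if metrics.negative_interval is not None:
                lo, hi = metrics.negative_interval
                sel = (tt >= lo) & (tt <= hi)
                ax.fill_between(tt[sel], np.clip(yy[sel], None, 0), 0,
                                color="blue", alpha=0.25)
    ax.axhline(0.0, color="k", lw=0.6)
    ax.set_xlabel("time after stimulus onset (s)")
    ax.set_ylabel("relative flow change (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_survey_frame(survey, frame_index, path=None):
    """One en-face survey frame, colormapped as relative flow change."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(survey.frames[frame_index], cmap="coolwarm",
                   vmin=0.95, vmax=1.05, origin="upper")
    fig.colorbar(im, ax=ax, label="relative flow")
    ax.set_title(f"frame {frame_index} "
                 f"(t = {frame_index * survey.frame_period:.2f} s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
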