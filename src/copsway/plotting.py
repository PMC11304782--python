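"""Plot a COP trajectory with its fitted probability ellipse."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ellipse import ProbabilityEllipseModel
from .trajectory import CopTrajectory


def plot_trajectory_with_ellipse(
    traj: CopTrajectory,
    model: ProbabilityEllipseModel | None = None,
    path: str | Path | None = None,
    coverage: float = 0.900,
):
    """Trajectory scatter (centered axes convention: +x left, +y anterior)
    with the coverage ellipse overlaid.  Returns the matplotlib figure; saves
    to ``path`` when given."""
    if model is None:
        model = ProbabilityEllipseModel(coverage=coverage).fit(traj)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(traj.x, traj.y, lw=0.4, alpha=0.6, color="tab:gray")
    boundary = model.boundary()
    ax.plot(boundary[:, 0], boundary[:, 1], color="tab:red", lw=1.5,
            label=f"{model.coverage:.1%} probability ellipse")
    ax.plot(*model.center_, marker="+", color="tab:red", ms=10)
    ax.set_xlabel("lateral COP x (mm, +left)")
    ax.set_ylabel("AP COP y (mm, +anterior)")
    ax.set_title(
        f"{traj.participant_id} / {traj.condition} / trial {traj.trial_index}\n"
        f"$\\delta$={model.long_diameter_:.1f} mm, "
        f"$\\vartheta$={model.declination_:.1f}$^\\circ$, "
        f"$\\varepsilon$={model.eccentricity_:.2f}"
    )
    ax.set_aspect("equal")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
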