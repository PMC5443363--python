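"""Sex-specific BMI-for-age chart rendering (EPS / PDF vector output).

Charts mimic the layout of standard BMI-for-age growth charts — age in
years on the x-axis (2 to <20), BMI on the y-axis — with the reference
percentile curves (default 5th, 50th, 85th, 95th) plus the two
severe-obesity cut-point curves at 120% and 140% of the 95th percentile.
Cross-sectional charts place one symbol per subject; longitudinal charts
connect each participant's visits with a line.

Rendering is split in two so tests never parse vector bytes: a chart is
first assembled into a :class:`Scene` (curve arrays, point coordinates,
polylines), and the scene is then drawn with matplotlib.  Output files are
reproducible: embedded creation timestamps are suppressed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
from matplotlib.figure import Figure

from .cohort import SubjectResult
from .lms import CurveSet, Sex, parse_sex

__all__ = [
    "ChartStyle",
    "ChartSpec",
    "Scene",
    "build_scene",
    "render_scene",
    "render_cross_sectional",
    "render_longitudinal",
    "default_output_name",
]

log = logging.getLogger(__name__)

Mode = Literal["cross_sectional", "longitudinal"]
FORMATS = ("eps", "pdf")


@dataclass(frozen=True)
class ChartStyle:
    """Symbol / line / font options (the customization knobs users tweak)."""

    symbol: str = "o"
    symbol_size: float = 12.0
    symbol_color: str = "#1f77b4"
    line_color: str = "#1f77b4"
    line_width: float = 1.0
    curve_color: str = "0.35"
    severe_curve_color: str = "#c44e52"
    font_size: float = 9.0
    color_by_id: bool = True  # longitudinal: cycle a color per child


@dataclass
class ChartSpec:
    """Everything needed to draw one sex-specific chart."""

    sex: Sex
    mode: Mode
    curves: CurveSet
    x_range: tuple[float, float] = (2.0, 20.0)
    y_min: float = 10.0
    y_max: float = 60.0
    output_format: str = "pdf"
    style: ChartStyle = field(default_factory=ChartStyle)
    title: str | None = None

    def __post_init__(self) -> None:
        self.sex = parse_sex(self.sex)
        if self.output_format not in FORMATS:
            raise ValueError(f"output_format must be one of {FORMATS}, got {self.output_format!r}")
        if self.curves.sex != self.sex:
            raise ValueError(f"curve set is for {self.curves.sex.value}, spec is {self.sex.value}")
        top_curve = max(float(np.max(v)) for v in self.curves.curves.values())
        if self.y_max <= top_curve:
            raise ValueError(
                f"y_max {self.y_max} must exceed the highest reference curve ({top_curve:.1f})"
            )


@dataclass
class Scene:
    """The assembled chart content, exposed for structural assertions."""

    spec: ChartSpec
    #: curve label -> (ages_years, bmi_values)
    curve_lines: dict[str, tuple[np.ndarray, np.ndarray]]
    #: cross-sectional points as (ages_years, bmi_values)
    points: tuple[np.ndarray, np.ndarray] | None = None
    #: longitudinal: list of (participant id, ages_years, bmi_values)
    trajectories: list[tuple[object, np.ndarray, np.ndarray]] = field(default_factory=list)
    n_clipped: int = 0


def default_output_name(sex: Sex | str, mode: Mode, fmt: str) -> str:
    """Standard chart file name, e.g. ``BMI_Graph_females_long.pdf``."""
    sex = parse_sex(sex)
    if mode not in ("cross_sectional", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")
    stem = f"BMI_Graph_{sex.value}s"
    if mode == "longitudinal":
        stem += "_long"
    return f"{stem}.{fmt}"


def _plottable(results: Sequence[SubjectResult], spec: ChartSpec) -> list[SubjectResult]:
    usable = [r for r in results if not math.isnan(r.bmi_kgm2)]
    if not usable:
        raise ValueError("no plottable results (all rows flagged or empty input)")
    wrong = {r.record.sex for r in usable if r.record.sex != spec.sex}
    if wrong:
        raise ValueError(
            f"results contain sex {[s.value if s else None for s in wrong]}, "
            f"chart is for {spec.sex.value}"
        )
    return usable


def build_scene(results: Sequence[SubjectResult], spec: ChartSpec) -> Scene:
    """Assemble a scene from scored results (single sex, mode per spec)."""
    usable = _plottable(results, spec)
    curve_lines = {
        label: (spec.curves.age_grid_years, values)
        for label, values in spec.curves.curves.items()
    }
    ages = np.array([r.record.age_y for r in usable], dtype=float)
    bmis = np.array([r.bmi_kgm2 for r in usable], dtype=float)
    n_clipped = int(np.sum(bmis > spec.y_max))
    if n_clipped:
        log.warning(
            "%d point(s) above y_max=%.1f kg/m^2 clipped to the axis limit", n_clipped, spec.y_max
        )
    bmis = np.minimum(bmis, spec.y_max)

    if spec.mode == "cross_sectional":
        return Scene(spec=spec, curve_lines=curve_lines, points=(ages, bmis), n_clipped=n_clipped)

    trajectories = []
    by_id: dict[object, list[tuple[float, float]]] = {}
    for age, bmi, r in sorted(zip(ages, bmis, usable), key=lambda t: (str(t[2].record.id), t[0])):
        by_id.setdefault(r.record.id, []).append((age, bmi))
    for pid, pts in by_id.items():
        a = np.array([p[0] for p in pts])
        b = np.array([p[1] for p in pts])
        if len(a) > 1 and np.any(np.diff(a) <= 0):
            raise ValueError(f"participant {pid!r} has duplicate or non-increasing visit ages")
        trajectories.append((pid, a, b))
    return Scene(spec=spec, curve_lines=curve_lines, trajectories=trajectories, n_clipped=n_clipped)


def render_scene(scene: Scene, path: str | Path) -> Path:
    """Draw a scene to an EPS or PDF file (format from the file suffix)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in FORMATS:
        raise ValueError(f"output file must end in .eps or .pdf, got {path.name!r}")
    spec = scene.spec
    style = spec.style

    fig = Figure(figsize=(6.5, 7.5))
    ax = fig.add_subplot(111)

    for label, (x, y) in scene.curve_lines.items():
        severe = "P95" in label and label != "P95"
        color = style.severe_curve_color if severe else style.curve_color
        ls = "--" if severe else "-"
        ax.plot(x, y, color=color, linestyle=ls, linewidth=1.0, zorder=2)
        ax.annotate(
            label,
            xy=(x[-1], min(y[-1], spec.y_max)),
            xytext=(3, 0),
            textcoords="offset points",
            fontsize=style.font_size - 1,
            color=color,
            va="center",
            annotation_clip=False,
        )

    if scene.points is not None:
        ax.scatter(
            scene.points[0],
            scene.points[1],
            s=style.symbol_size,
            marker=style.symbol,
            c=style.symbol_color,
            alpha=0.6,
            linewidths=0,
            zorder=3,
        )
    cmap = matplotlib.colormaps["tab20"]
    for i, (pid, x, y) in enumerate(scene.trajectories):
        color = cmap(i % 20) if style.color_by_id else style.line_color
        ax.plot(
            x,
            y,
            marker="o",
            markersize=max(style.symbol_size**0.5, 3.0),
            color=color,
            linewidth=style.line_width,
            zorder=3,
        )

    sex_word = "Females" if spec.sex == Sex.FEMALE else "Males"
    ax.set_title(spec.title or f"BMI-for-Age: {sex_word}", fontsize=style.font_size + 2)
    ax.set_xlabel("Age (years)", fontsize=style.font_size)
    ax.set_ylabel("BMI (kg/m$^2$)", fontsize=style.font_size)
    ax.set_xlim(spec.x_range)
    ax.set_ylim(spec.y_min, spec.y_max)
    ax.set_xticks(np.arange(math.ceil(spec.x_range[0]), math.floor(spec.x_range[1]) + 1, 1))
    ax.tick_params(labelsize=style.font_size - 1)
    ax.grid(True, linewidth=0.3, alpha=0.5)

    if fmt == "pdf":
        fig.savefig(path, format="pdf", metadata={"CreationDate": None})
    else:
        fig.savefig(path, format="eps")
        _strip_eps_timestamp(path)
    return path


def render_cross_sectional(
    results: Sequence[SubjectResult], spec: ChartSpec, path: str | Path
) -> Scene:
    """Render a one-point-per-subject chart; returns the scene drawn."""
    if spec.mode != "cross_sectional":
        raise ValueError("spec.mode must be 'cross_sectional'")
    scene = build_scene(results, spec)
    render_scene(scene, path)
    return scene


def render_longitudinal(
    results: Sequence[SubjectResult], spec: ChartSpec, path: str | Path
) -> Scene:
    """Render a one-trajectory-per-participant chart; returns the scene."""
    if spec.mode != "longitudinal":
        raise ValueError("spec.mode must be 'longitudinal'")
    scene = build_scene(results, spec)
    render_scene(scene, path)
    return scene


def _strip_eps_timestamp(path: Path) -> None:
    # the ps backend embeds %%CreationDate and the output path in %%Title;
    # normalize both so identical inputs give byte-identical files
    text = path.read_text()
    text = re.sub(r"%%CreationDate: [^\n]*\n", "", text, count=1)
    text = re.sub(r"%%Title: [^\n]*\n", "%%Title: BMI-for-age chart\n", text, count=1)
    path.write_text(text)
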