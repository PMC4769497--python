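"""Rendering of per-run QC outputs: summary.txt, its JSON twin, TSV table
dumps, and the eight per-read-type plots.

Every plot is drawn from the finalized statistics structures, and the same
numbers can be dumped as TSV (``tables=True``) so plot content is
assertable without parsing images.  Output layout mirrors the per-run
convention: one subfolder per run_id under the output root.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .extract import FILE_TOKEN
from .fast5 import READ_TYPES
from .stats import (
    LENGTH_BIN_WIDTH,
    ReadTypeStats,
    RunStats,
    finalize,
    per_position_mean_quality,
    yield_curve,
)

__all__ = ["PLOT_NAMES", "write_reports", "summary_text"]

#: The eight per-read-type plot stems, ``{seq}`` resolved per read type.
PLOT_NAMES = (
    "length_histogram",
    "content_per_pos",
    "gc_histogram",
    "yield",
    "quality_histogram",
    "quality_per_pos",
    "reads_per_channel",
    "yield_per_channel",
)

_BASE_ORDER = ("A", "C", "G", "T", "N")


def summary_text(run_id: str, per_type: dict, uncalled_files: int) -> str:
    """Render one run's summary as UTF-8 ``key: value`` lines."""
    lines = [f"run: {run_id}"]
    for rt in READ_TYPES:
        if rt not in per_type:
            continue
        s = per_type[rt]
        lines.append(f"[{FILE_TOKEN[rt]}]")
        if s.get("no_reads"):
            lines.append("reads: no reads")
            continue
        lines.append(f"reads: {s['reads']}")
        lines.append(f"nucleotides: {s['nucleotides']}")
        lines.append(f"mean length: {s['mean_length']:.2f}")
        lines.append(f"min length: {s['min_length']}")
        lines.append(f"max length: {s['max_length']}")
        for b in _BASE_ORDER:
            lines.append(
                f"{b} count: {s['base_counts'][b]} ({s['base_percent'][b]:.2f}%)"
            )
        gc = "undefined" if s.get("gc_undefined") else f"{s['gc_percent']:.2f}"
        lines.append(f"%GC: {gc}")
        lines.append(f"mean quality: {s['mean_quality']:.2f}")
    lines.append(f"uncalled files: {uncalled_files}")
    return "\n".join(lines) + "\n"


def _table_rows(stats: ReadTypeStats, plot: str) -> tuple[list[str], list[tuple]]:
    if plot == "length_histogram":
        return ["length_bin_start", "count"], [
            (b * LENGTH_BIN_WIDTH, c) for b, c in sorted(stats.length_histogram.items())
        ]
    if plot == "content_per_pos":
        prof = stats.position_profile
        rows = [
            (p, *(int(prof.base_counts[i, p]) for i in range(5)))
            for p in range(len(prof))
            if prof.obs_count[p] > 0
        ]
        return ["position", *_BASE_ORDER], rows
    if plot == "gc_histogram":
        return ["gc_percent", "count"], sorted(stats.gc_histogram.items())
    if plot == "yield":
        return ["time_s", "cumulative_nucleotides"], [
            (f"{t:.0f}", n) for t, n in yield_curve(stats)
        ]
    if plot == "quality_histogram":
        return ["mean_quality", "count"], sorted(stats.quality_histogram.items())
    if plot == "quality_per_pos":
        return ["position", "mean_quality"], [
            (p, f"{q:.4f}") for p, q in per_position_mean_quality(stats.position_profile)
        ]
    if plot == "reads_per_channel":
        return ["channel", "reads"], sorted(stats.reads_per_channel.items())
    if plot == "yield_per_channel":
        return ["channel", "nucleotides"], sorted(stats.nucleotides_per_channel.items())
    raise ValueError(f"unknown plot {plot!r}")


def _render_plot(stats: ReadTypeStats, plot: str, token: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    header, rows = _table_rows(stats, plot)
    if plot == "content_per_pos":
        xs = [r[0] for r in rows]
        total = stats.position_profile.obs_count
        for i, b in enumerate(_BASE_ORDER):
            ax.plot(xs, [r[1 + i] / total[r[0]] * 100 for r in rows], label=b, lw=0.8)
        ax.set_ylabel("base content (%)")
        ax.legend(ncol=5, fontsize=8)
    elif plot in ("length_histogram", "gc_histogram", "quality_histogram"):
        xs = [float(r[0]) for r in rows]
        ys = [r[1] for r in rows]
        width = {"length_histogram": LENGTH_BIN_WIDTH}.get(plot, 1.0)
        ax.bar(xs, ys, width=width * 0.9, align="edge")
        ax.set_ylabel("reads")
    elif plot in ("reads_per_channel", "yield_per_channel"):
        ax.bar([r[0] for r in rows], [r[1] for r in rows], width=0.9)
        ax.set_ylabel("reads" if plot == "reads_per_channel" else "nucleotides")
        ax.set_xlabel("channel")
    else:  # yield, quality_per_pos
        ax.plot([float(r[0]) for r in rows], [float(r[1]) for r in rows], lw=1.0)
        ax.set_ylabel(
            "cumulative nucleotides" if plot == "yield" else "mean quality"
        )
    ax.set_xlabel(
        {
            "length_histogram": "read length (nt)",
            "content_per_pos": "position in read",
            "gc_histogram": "read %GC",
            "yield": "run time (s)",
            "quality_histogram": "mean read quality (Phred)",
            "quality_per_pos": "position in read",
        }.get(plot, ax.get_xlabel())
    )
    ax.set_title(f"{token} {plot.replace('_', ' ')}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_reports(
    stats: RunStats,
    out_root: str | Path,
    *,
    plots: bool = True,
    tables: bool = False,
    image_format: str = "png",
) -> dict:
    """Write per-run summary.txt + summary.json and, optionally, the eight
    per-read-type plots and/or their TSV table dumps.  Returns the
    finalized report dict."""
    report = finalize(stats)
    root = Path(out_root)
    root.mkdir(parents=True, exist_ok=True)
    if not report["runs"]:
        # no reads anywhere: still leave a summary behind
        (root / "summary.txt").write_text(
            "no reads\n" f"uncalled files: {report['uncalled_files']}\n"
        )
        (root / "summary.json").write_text(json.dumps(report, indent=2) + "\n")
        return report
    for run_id, per_type in report["runs"].items():
        run_dir = root / run_id
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "summary.txt").write_text(
            summary_text(run_id, per_type, report["uncalled_files"])
        )
        (run_dir / "summary.json").write_text(
            json.dumps(
                {"run": run_id, "uncalled_files": report["uncalled_files"], **per_type},
                indent=2,
            )
            + "\n"
        )
        for rt in per_type:
            rts = stats.runs[run_id][rt]
            if rts.n_reads == 0:
                continue
            token = FILE_TOKEN[rt]
            if tables:
                tdir = run_dir / "tables"
                tdir.mkdir(exist_ok=True)
                for plot in PLOT_NAMES:
                    header, rows = _table_rows(rts, plot)
                    text = "\t".join(header) + "\n"
                    text += "".join(
                        "\t".join(str(v) for v in row) + "\n" for row in rows
                    )
                    (tdir / f"{token}_{plot}.tsv").write_text(text)
            if plots:
                for plot in PLOT_NAMES:
                    _render_plot(
                        rts, plot, token, run_dir / f"{token}_{plot}.{image_format}"
                    )
    return report
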