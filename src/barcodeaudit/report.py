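"""Render audit results to TSV/JSON artifacts.

Distances are proportions everywhere in memory; this module is the only
place they become percentages.  Species-pair and histogram tables round
half-up to 1 decimal percent; global stratum means use 2 decimals.
Re-rendering the same report is byte-identical (stable sort orders,
fixed rounding), so diffs between runs reflect the data, not the code.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .audit import AuditReport, Histogram
from .seqio import write_tsv

__all__ = [
    "format_percent",
    "render_table1",
    "render_histograms",
    "render_manifest",
    "write_report_bundle",
    "ReportBundle",
]


def format_percent(proportion: float, decimals: int = 1) -> str:
    """Render a proportion as percent, half-up at ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(proportion * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReportBundle:
    """Paths of the emitted artifacts plus run metadata."""

    outdir: Path
    files: tuple[str, ...]
    metadata: dict


def render_table1(report: AuditReport, path: str | Path) -> None:
    """Low-divergence species pairs: species1, species2, min p.d. % (1 dp)."""
    rows = [
        [s1, s2, format_percent(d)] for s1, s2, d in report.low_divergence
    ]
    write_tsv(rows, ["species1", "species2", "min_pd_percent"], path)


def _hist_rows(h: Histogram) -> list[list[str]]:
    return [
        [format_percent(lo), format_percent(hi), str(c)]
        for (lo, hi), c in zip(h.edges(), h.counts)
    ]


def render_histograms(report: AuditReport, nn_path: str | Path, mpd_path: str | Path) -> None:
    """0.5%-class histograms of NN distances and MPDs, plot-ready TSVs."""
    cols = ["bin_lo_percent", "bin_hi_percent", "n_species"]
    write_tsv(_hist_rows(report.nn_hist), cols, nn_path)
    write_tsv(_hist_rows(report.mpd_hist), cols, mpd_path)


def render_species_audit(report: AuditReport, path: str | Path) -> None:
    rows = []
    for a in report.audits:
        rows.append(
            [
                a.species,
                a.n_specimens,
                "" if a.mpd is None else format_percent(a.mpd),
                a.nn_species or "",
                "" if a.nn_distance is None else format_percent(a.nn_distance),
                a.n_subclusters,
                ";".join(sorted(a.flags)),
            ]
        )
    write_tsv(
        rows,
        [
            "species",
            "n_specimens",
            "mpd_percent",
            "nn_species",
            "nn_distance_percent",
            "n_subclusters",
            "flags",
        ],
        path,
    )


def render_sharing(report: AuditReport, path: str | Path) -> None:
    rows = [
        [p.species1, p.species2, p.n_pairs, "regular" if p.regular else "one-off",
         ";".join(f"{a}~{b}" for a, b in p.specimen_pairs)]
        for p in report.sharing
    ]
    write_tsv(
        rows,
        ["species1", "species2", "n_zero_pairs", "pattern", "specimen_pairs"],
        path,
    )


def render_deep_splits(report: AuditReport, path: str | Path) -> None:
    rows = []
    for sp in sorted(report.deep_splits):
        s = report.deep_splits[sp]
        rows.append(
            [
                sp,
                format_percent(s.mpd),
                s.n_subclusters,
                "single-outlier" if s.singleton_outlier else "multi-individual",
                "|".join(",".join(c) for c in s.subclusters),
            ]
        )
    write_tsv(
        rows,
        ["species", "mpd_percent", "n_subclusters", "pattern", "subclusters"],
        path,
    )


def render_global_stats(report: AuditReport, path: str | Path) -> None:
    out = {}
    for name, st in report.stats.items():
        out[name] = {
            "mean_percent": None if st.n == 0 else format_percent(st.mean, 2),
            "mean": None if st.n == 0 else st.mean,
            "se": None if st.n == 0 else st.se,
            "se_defined": st.se_defined,
            "n_comparisons": st.n,
        }
    out["resolution"] = {
        "n_diagnosable": report.n_diagnosable,
        "fraction": report.resolution,
        "percent": format_percent(report.resolution, 1),
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")


def render_manifest(bundle: ReportBundle, path: str | Path) -> None:
    """Manifest JSON naming every emitted file plus run metadata."""
    with open(path, "w") as fh:
        json.dump(
            {"files": sorted(bundle.files), "metadata": bundle.metadata},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def write_report_bundle(
    report: AuditReport, outdir: str | Path, extra_metadata: dict | None = None
) -> ReportBundle:
    """Write the full artifact set and its manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emitted = {
        "species_audit.tsv": render_species_audit,
        "low_divergence_pairs.tsv": render_table1,
        "sharing_pairs.tsv": render_sharing,
        "deep_splits.tsv": render_deep_splits,
        "global_stats.json": render_global_stats,
    }
    for name, fn in emitted.items():
        fn(report, outdir / name)
    render_histograms(report, outdir / "nn_hist.tsv", outdir / "mpd_hist.tsv")
    files = tuple(sorted(list(emitted) + ["nn_hist.tsv", "mpd_hist.tsv", "manifest.json"]))
    from . import __version__

    metadata = {
        "version": __version__,
        "params": dict(report.params),
        "counts": dict(report.counts),
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    bundle = ReportBundle(outdir=outdir, files=files, metadata=metadata)
    render_manifest(bundle, outdir / "manifest.json")
    return bundle
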