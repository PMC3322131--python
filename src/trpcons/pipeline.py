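"""End-to-end orchestration: ingest -> extract -> conserve -> wheel ->
composition -> pI -> motif -> clock, with one config and one seed.

Outputs are plain TSV plus a JSON run manifest. Nothing in the outputs
depends on wall-clock time, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .charge import PKA_SETS, absence_count, composition, region_charge_report
from .clock import ClockPoint, compare_proteins, fit_clock, lineage_rate
from .conservation import conservation_report, kruskal_wallis, region_distances
from .io import (
    Alignment,
    apply_manifest,
    load_region_table,
    read_alignment,
    read_manifest,
    write_tsv,
)
from .motif import MotifPattern, TBS1_PATTERN, scan
from .regions import RegionSlice, build_column_map, extract_region, filter_slices
from .wheel import best_arc_coverage, project_wheel, quadrant_counts, superimpose


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    alignment: str
    reference_id: str
    out_dir: str
    manifest: Optional[str] = None
    region_table: Optional[str] = None  # None = packaged TRPV1 table
    steps: int = 18
    turns: int = 7
    pka_set: str = "bjellqvist"
    motif_pattern: str = TBS1_PATTERN
    motif_min_fraction: float = 0.8
    arc_widths: dict[str, float] = field(
        default_factory=lambda: {"TBS-1": 120.0, "TBS-2": 180.0}
    )
    min_coverage: float = 0.5
    bootstrap_replicates: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _check_inputs(config: RunConfig) -> None:
    for label, path in (
        ("alignment", config.alignment),
        ("manifest", config.manifest),
        ("region table", config.region_table),
    ):
        if path is not None and not Path(path).exists():
            raise StageError("config", f"{label} file not found: {path}")
    if config.pka_set not in PKA_SETS:
        raise StageError(
            "config", f"unknown pKa set {config.pka_set!r}; know {sorted(PKA_SETS)}"
        )


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Writes slices.tsv, fig3.tsv, wheel.tsv, comp.tsv, pi.tsv, hits.tsv,
    clock.tsv, run_manifest.json and run.log. A stage failure raises
    :class:`StageError` naming the stage, before partial outputs of later
    stages exist.
    """
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"trpcons {__version__}",
        f"seed {config.seed}",
        f"reference {config.reference_id}",
    ]

    # --- ingest -----------------------------------------------------------
    try:
        alignment = read_alignment(config.alignment)
        if config.manifest:
            manifest = read_manifest(config.manifest)
            alignment = Alignment(apply_manifest(list(alignment), manifest))
        else:
            manifest = None
        regions = load_region_table(config.region_table)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", str(exc)) from exc

    # --- extract ----------------------------------------------------------
    try:
        cmap = build_column_map(alignment, config.reference_id)
        slices_by_region = {}
        slice_rows = []
        for region in regions:
            all_slices = extract_region(alignment, cmap, region)
            kept = filter_slices(all_slices, config.min_coverage)
            excluded = sorted(
                {s.species for s in all_slices} - {s.species for s in kept}
            )
            if excluded:
                log_lines.append(
                    f"region {region.name}: excluded {','.join(excluded)}"
                )
            slices_by_region[region.name] = kept
            for s in all_slices:
                slice_rows.append(dataclasses.asdict(s))
        write_tsv(slice_rows, out / "slices.tsv")
    except Exception as exc:
        raise StageError("extract", str(exc)) from exc

    # --- conserve ---------------------------------------------------------
    try:
        region_sets = []
        groups = {}
        for region in regions:
            kept = slices_by_region[region.name]
            if len(kept) < 2:
                log_lines.append(f"region {region.name}: <2 sequences, skipped")
                continue
            rs = region_distances(
                kept,
                bootstrap_replicates=config.bootstrap_replicates or None,
                seed=config.seed,
            )
            region_sets.append(rs)
            groups[region.name] = [d.p for d in rs.distances if d.defined]
        # pooled full-length series: each whole alignment row as one slice
        full_slices = [
            RegionSlice(
                region="FL",
                species=rec.id,
                columns=rec.sequence,
                subsequence=rec.ungapped,
                coverage=1.0,
            )
            for rec in alignment
        ]
        region_sets.append(region_distances(full_slices))
        rows = conservation_report(region_sets)
        write_tsv(rows, out / "fig3.tsv")
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            log_lines.append(
                f"kruskal-wallis H={kw.H:.4f} df={kw.df} p={kw.p_value:.3g}"
            )
    except Exception as exc:
        raise StageError("conserve", str(exc)) from exc

    # --- wheel ------------------------------------------------------------
    try:
        wheel_rows = []
        for name, width in config.arc_widths.items():
            kept = [s for s in slices_by_region.get(name, []) if s.subsequence]
            if not kept:
                log_lines.append(f"wheel {name}: no usable slices, skipped")
                continue
            projections = [
                project_wheel(s, config.steps, config.turns) for s in kept
            ]
            pooled = superimpose(projections)
            arc = best_arc_coverage([a for a, _, _ in pooled], width)
            quads = quadrant_counts([a for a, _, _ in pooled])
            wheel_rows.append(
                {
                    "region": name,
                    "width": width,
                    "arc_start": arc.start,
                    "covered": arc.covered,
                    "total_positive": arc.total,
                    "fraction": arc.fraction,
                    "q1": quads.counts[0],
                    "q2": quads.counts[1],
                    "q3": quads.counts[2],
                    "q4": quads.counts[3],
                }
            )
        write_tsv(
            wheel_rows, out / "wheel.tsv",
            columns=["region", "width", "arc_start", "covered", "total_positive",
                     "fraction", "q1", "q2", "q3", "q4"],
        )
    except Exception as exc:
        raise StageError("wheel", str(exc)) from exc

    # --- composition & pI -------------------------------------------------
    try:
        comp_rows = []
        pi_rows = []
        pkas = PKA_SETS[config.pka_set]
        for name in config.arc_widths:
            kept = [s for s in slices_by_region.get(name, []) if s.subsequence]
            if not kept:
                continue
            profile = composition(kept)
            lacking, total = absence_count(kept, {"E", "D"})
            for aa, freq in profile.frequencies.items():
                comp_rows.append(
                    {"region": name, "residue": aa, "percent": 100.0 * freq}
                )
            comp_rows.append(
                {"region": name, "residue": "no_E_or_D", "percent": float(lacking)}
            )
            comp_rows.append(
                {"region": name, "residue": "n_species", "percent": float(total)}
            )
            rows_pi, summary = region_charge_report(kept, pkas)
            pi_rows.extend(rows_pi)
            for stat, value in summary.items():
                pi_rows.append({"region": name, "species": f"<{stat}>", "pI": value})
        write_tsv(comp_rows, out / "comp.tsv",
                  columns=["region", "residue", "percent"])
        write_tsv(pi_rows, out / "pi.tsv", columns=["region", "species", "pI"])
    except Exception as exc:
        raise StageError("composition", str(exc)) from exc

    # --- motif ------------------------------------------------------------
    try:
        pattern = MotifPattern(pattern=config.motif_pattern)
        hit_rows = []
        for rec in alignment:
            for offset, fraction in scan(
                rec.ungapped, pattern, min_fraction=config.motif_min_fraction
            ):
                hit_rows.append(
                    {
                        "id": rec.id,
                        "offset_1based": offset + 1,
                        "fraction": fraction,
                    }
                )
        write_tsv(hit_rows, out / "hits.tsv",
                  columns=["id", "offset_1based", "fraction"])
    except Exception as exc:
        raise StageError("motif", str(exc)) from exc

    # --- clock ------------------------------------------------------------
    try:
        clock_rows = []
        if manifest is not None and "divergence_time_mya" in manifest.columns:
            timed = manifest.dropna(subset=["divergence_time_mya"])
            points = []
            ref = alignment.get(config.reference_id)
            for (group, time), sub in timed.groupby(
                ["group", "divergence_time_mya"], sort=True
            ):
                ids = [i for i in sub["id"] if i != config.reference_id]
                pairs = [(ref, alignment.get(i)) for i in ids
                         if i in alignment.ids]
                if not pairs or float(time) < 0:
                    continue
                rate = lineage_rate(pairs, alignment)
                points.append(
                    ClockPoint(
                        label=str(group),
                        changes_per_100=rate,
                        divergence_time_mya=float(time),
                        pairs=tuple((a.id, b.id) for a, b in pairs),
                    )
                )
            for p in points:
                clock_rows.append(
                    {
                        "label": p.label,
                        "divergence_time_mya": p.divergence_time_mya,
                        "changes_per_100": p.changes_per_100,
                        "n_pairs": len(p.pairs),
                    }
                )
            times = {p.divergence_time_mya for p in points}
            if len(times) >= 2:
                fit = fit_clock(points, anchor_zero=True)
                clock_rows.append(
                    {
                        "label": "<fit_slope>",
                        "divergence_time_mya": float("nan"),
                        "changes_per_100": fit.slope,
                        "n_pairs": fit.n_points,
                    }
                )
                clock_rows.append(
                    {
                        "label": "<fit_time_axis_intercept>",
                        "divergence_time_mya": fit.time_axis_intercept,
                        "changes_per_100": 0.0,
                        "n_pairs": fit.n_points,
                    }
                )
        write_tsv(clock_rows, out / "clock.tsv",
                  columns=["label", "divergence_time_mya", "changes_per_100",
                           "n_pairs"])
    except Exception as exc:
        raise StageError("clock", str(exc)) from exc

    manifest_data = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.suffix in {".tsv"}
        ),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest_data, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
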