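"""End-to-end mini-barcode design pipeline and report writers.

Stages: (1) compare the genome pair (substitutions, indels, inversions);
(2) sliding-window diversity scan and hotspot calling; (3) per-marker
variability statistics and nearest-neighbour discrimination; (4) shortest
mini-barcode search per marker. The hotspot → marker hand-off is manual by
design: the pipeline reports hotspot coordinates, and the marker alignments
it evaluates are supplied by the user (resequencing panels or slices of a
multi-genome alignment). Partial configurations run whichever stages their
inputs allow.

All TSV/JSON outputs carry a header comment naming the tool version and the
parameters used; coordinates in files are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .barcode_discrimination import (
    k2p_matrix,
    near_neighbour,
    pm_length_curve,
    shortest_minibarcode,
)
from .core_io import (
    AlignedPair,
    FeatureTable,
    MarkerAlignment,
    SpeciesMap,
    read_alignment,
    read_feature_table,
    read_species_map,
)
from .diversity_scan import (
    DEFAULT_HOTSPOT_THRESHOLD,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    find_hotspots,
    marker_stats,
    sliding_pi,
)
from .genome_comparison import (
    classify_substitutions,
    detect_indels,
    detect_inversions,
    tstv_by_region,
)

logger = logging.getLogger("minibarcode")


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    output_dir: str = "minibarcode_out"
    genome_pair: str | None = None
    reference_id: str | None = None
    features: str | None = None
    markers: list[dict] = field(default_factory=list)  # {name, alignment}
    species_map: str | None = None
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD
    start: int = 50
    increment: int = 10
    tie_rule: str = "all"
    inversion_masking: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for p in self._input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.step <= self.window:
            raise ValueError("need 0 < step <= window")
        if self.start < 1 or self.increment < 1:
            raise ValueError("start and increment must be positive")
        if self.tie_rule not in ("all", "any"):
            raise ValueError("tie_rule must be 'all' or 'any'")

    def _input_paths(self) -> list[str]:
        paths = [p for p in (self.genome_pair, self.features, self.species_map) if p]
        paths.extend(m["alignment"] for m in self.markers)
        return paths


@dataclass
class RunManifest:
    version: str
    parameters: dict
    input_checksums: dict[str, str]
    outputs: dict[str, str]  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    stages_completed: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _header(params: dict) -> str:
    ptxt = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# minibarcode v{__version__} {ptxt}\n"


def write_tsv(df, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params))
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"tool": f"minibarcode v{__version__}", "parameters": params,
                   "result": obj}, fh, indent=2)


# ---------------------------------------------------------------------------
# stage output writers (also used by the single-stage CLI commands)
# ---------------------------------------------------------------------------

def write_comparison_outputs(
    pair: AlignedPair,
    features: FeatureTable | None,
    outdir: Path,
    mask_inversions: bool = True,
) -> list[Path]:
    import pandas as pd

    params = {"inversion_masking": mask_inversions}
    inversions = detect_inversions(pair)
    events, summary = classify_substitutions(
        pair, features, mask_inversions=mask_inversions, inversions=inversions
    )
    out: list[Path] = []

    df = pd.DataFrame(
        [
            {
                "ref_pos_1based": e.ref_pos + 1,
                "ref_base": e.ref_base,
                "other_base": e.other_base,
                "collapsed_type": e.collapsed_type,
                "class": "transition" if e.transition else "transversion",
                "region": e.region_category,
            }
            for e in events
        ],
        columns=["ref_pos_1based", "ref_base", "other_base", "collapsed_type",
                 "class", "region"],
    )
    p = outdir / "substitutions.tsv"
    write_tsv(df, p, params)
    out.append(p)

    p = outdir / "substitution_summary.json"
    write_json(
        {
            "n_total": summary.n_total,
            "n_transition": summary.n_transition,
            "n_transversion": summary.n_transversion,
            "ts_tv": summary.ts_tv,
            "spectrum": summary.spectrum,
            "by_region": tstv_by_region(summary).to_dict(orient="records"),
        },
        p,
        params,
    )
    out.append(p)

    indel_events, histogram = detect_indels(pair, features)
    df = pd.DataFrame(
        [
            {
                "ref_pos_1based": e.ref_pos + 1,
                "length": e.length,
                "gap_carrier": e.carrier,
                "region": e.region_category,
            }
            for e in indel_events
        ],
        columns=["ref_pos_1based", "length", "gap_carrier", "region"],
    )
    p = outdir / "indels.tsv"
    write_tsv(df, p, {"histogram": histogram})
    out.append(p)

    df = pd.DataFrame(
        [
            {
                "loop_start_1based": e.loop_start + 1,
                "loop_end_1based": e.loop_end,
                "loop_length": e.loop_length,
                "stem_length": e.stem_length,
                "stem_5prime": e.stem_sequences[0],
                "stem_3prime": e.stem_sequences[1],
            }
            for e in inversions
        ],
        columns=["loop_start_1based", "loop_end_1based", "loop_length",
                 "stem_length", "stem_5prime", "stem_3prime"],
    )
    p = outdir / "inversions.tsv"
    write_tsv(df, p, {})
    out.append(p)
    return out


def write_diversity_outputs(
    pair_or_aln, outdir: Path, window: int, step: int, threshold: float
) -> list[Path]:
    import pandas as pd

    params = {"window": window, "step": step, "threshold": threshold}
    track = sliding_pi(pair_or_aln, window, step)
    out: list[Path] = []
    df = track.table.copy()
    df["window_start_1based"] = df.pop("window_start") + 1
    df["midpoint_1based"] = df.pop("midpoint") + 1
    df = df[["window_start_1based", "midpoint_1based", "n_sites_compared", "pi"]]
    p = outdir / "diversity_track.tsv"
    write_tsv(df, p, params)
    out.append(p)

    hotspots = find_hotspots(track, threshold)
    df = pd.DataFrame(
        [
            {
                "start_1based": h.start + 1,
                "end_1based": h.end,
                "peak_pi": h.peak_pi,
                "threshold": h.threshold,
            }
            for h in hotspots
        ],
        columns=["start_1based", "end_1based", "peak_pi", "threshold"],
    )
    p = outdir / "hotspots.tsv"
    write_tsv(df, p, params)
    out.append(p)
    return out


def write_marker_outputs(
    aln: MarkerAlignment,
    species: SpeciesMap,
    outdir: Path,
    start: int,
    increment: int,
    tie_rule: str,
) -> tuple[list[Path], dict]:
    import pandas as pd

    params = {"marker": aln.marker_name, "start": start,
              "increment": increment, "tie_rule": tie_rule}
    out: list[Path] = []
    prefix = aln.marker_name or "marker"

    stats = marker_stats(aln)
    p = outdir / f"{prefix}.marker_stats.tsv"
    write_tsv(pd.DataFrame([dataclasses.asdict(stats)]), p, params)
    out.append(p)

    dm = k2p_matrix(aln)
    p = outdir / f"{prefix}.distances.tsv"
    with open(p, "w") as fh:
        fh.write(_header(params))
        dm.to_frame().to_csv(fh, sep="\t")
    out.append(p)

    disc = near_neighbour(dm, species, tie_rule)
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "nearest": ",".join(s.nearest),
                "min_distance": s.min_distance,
                "success": s.success,
            }
            for s in disc.samples
        ]
    )
    p = outdir / f"{prefix}.discrimination.tsv"
    write_tsv(df, p, params)
    out.append(p)

    curve = pm_length_curve(aln, species, tie_rule=tie_rule)
    p = outdir / f"{prefix}.pm_curve.tsv"
    write_tsv(curve, p, params)
    out.append(p)

    result = shortest_minibarcode(aln, species, start, increment, tie_rule=tie_rule)
    p = outdir / f"{prefix}.minibarcode.json"
    write_json(
        {
            "marker": result.marker_name,
            "shortest_length_bp": result.shortest_length,
            "window_start_1based": result.best_window_start + 1,
            "window_end_1based": result.best_window_start + result.shortest_length,
            "pm_at_shortest": result.pm_at_shortest,
            "full_length_pm": result.full_length_pm,
        },
        p,
        params,
    )
    out.append(p)
    summary_row = {
        "marker": prefix,
        "max_discrimination_success_pm": disc.pm,
        "shortest_length_bp": result.shortest_length,
    }
    return out, summary_row


def run_design(config: RunConfig) -> RunManifest:
    """Run every stage the configuration's inputs allow; returns the manifest."""
    import pandas as pd

    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        parameters={
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
        },
        input_checksums={p: _sha256(p) for p in config._input_paths()},
        outputs={},
    )
    created: list[Path] = []

    pair = None
    if config.genome_pair:
        pair = read_alignment(
            config.genome_pair, kind="genome-pair", reference_id=config.reference_id
        )
        features = read_feature_table(config.features) if config.features else None
        created += write_comparison_outputs(
            pair, features, outdir, mask_inversions=config.inversion_masking
        )
        manifest.stages_completed.append("genome_comparison")
        created += write_diversity_outputs(
            pair, outdir, config.window, config.step, config.threshold
        )
        manifest.stages_completed.append("diversity_scan")
    else:
        manifest.warnings.append("no genome pair supplied; comparison and scan skipped")

    if config.markers and config.species_map:
        species = read_species_map(config.species_map)
        summary_rows = []
        for spec in config.markers:
            aln = read_alignment(
                spec["alignment"], kind="marker", marker_name=spec.get("name")
            )
            files, row = write_marker_outputs(
                aln, species, outdir, config.start, config.increment, config.tie_rule
            )
            created += files
            summary_rows.append(row)
        p = outdir / "summary.tsv"
        write_tsv(pd.DataFrame(summary_rows), p,
                  {"tie_rule": config.tie_rule, "start": config.start,
                   "increment": config.increment})
        created.append(p)
        manifest.stages_completed.append("barcode_discrimination")
    else:
        manifest.warnings.append(
            "no marker alignments + species map supplied; discrimination skipped"
        )

    manifest.outputs = {str(p): _sha256(p) for p in created}
    manifest.write(outdir / "manifest.json")
    return manifest
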