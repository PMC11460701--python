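"""End-to-end orchestration: catalog -> detect -> features -> RBP ->
enrichment/clustering/quantification, with a checksummed output manifest.

All randomness flows from one root seed via fixed per-stage offsets, so two
runs with the same inputs and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from flexiscan import annotations, cluster, detect, features, quantify, rbp, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gtf: str
    genome_fasta: str
    alignments: str
    rbp_sites: str
    output_dir: str
    standards: Optional[str] = None
    conservation: Optional[str] = None
    sample_id: str = "sample"
    short_threshold: int = 300
    end_window: int = 3
    rpm_cuts: tuple = (0.002, 0.01)
    min_flexis: int = 30
    min_pct_class: float = 1.0
    min_pct_subset: float = 2.0
    alpha: float = 0.05
    fc_threshold: float = 1.5
    phastcons_cuts: tuple = (0.75, 0.99)
    n_clusters: int = 6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("short_threshold", "end_window", "min_flexis", "alpha",
                     "fc_threshold", "n_clusters"):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be positive")
        for name in ("gtf", "genome_fasta", "alignments", "rbp_sites"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns (and writes) a manifest
    mapping each output table to its sha256 checksum."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = path

    # ------------------------------------------------------------- catalog
    try:
        catalog = annotations.build_intron_catalog(
            config.gtf, short_threshold=config.short_threshold
        )
        catalog = annotations.flag_splice_relationships(catalog, config.gtf)
        catalog.to_tsv(outdir / "introns.tsv")
        outputs["introns.tsv"] = outdir / "introns.tsv"
    except Exception as e:  # noqa: BLE001
        raise StageError("catalog", e)

    # -------------------------------------------------------------- detect
    try:
        fragments = list(detect.fragments_from_alignments(config.alignments))
        calls = detect.call_flexis(
            fragments, catalog, config.sample_id, end_window=config.end_window
        )
        _write("flexi_calls.tsv", detect.calls_to_frame(calls))
        _write(
            "end_offset_profile.tsv",
            detect.end_offset_profile(calls.values(), config.end_window).reset_index(),
        )
        _write(
            "length_fraction_hist.tsv",
            detect.length_fraction_histogram(fragments, catalog, set(calls)),
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("detect", e)

    # ------------------------------------------------------------ features
    try:
        import pyfaidx

        genome = pyfaidx.Fasta(config.genome_fasta)
        track = (
            features.ConservationTrack.from_bedgraph(config.conservation)
            if config.conservation
            else None
        )
        feat = features.compute_features(catalog, genome, track=track)
        _write("features.tsv", feat)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("features", e)

    # ----------------------------------------------------------------- rbp
    try:
        sites = rbp.read_site_bed(config.rbp_sites)
        profiles = rbp.intersect_sites(catalog, sites)
        _write("rbp_profiles.tsv", rbp.profiles_to_frame(profiles))
        flexi_ids = set(calls)
        flexi_profiles = {i: p for i, p in profiles.items() if i in flexi_ids}
        ranked = rbp.rbps_with_min_flexis(flexi_profiles, min_count=config.min_flexis)
        _write("rbps_min_flexis.tsv", ranked)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("rbp", e)

    # ---------------------------------------------------- enrichment + cluster
    try:
        other_short = {
            i: p
            for i, p in profiles.items()
            if i not in flexi_ids and catalog[i].size_class == "short"
        }
        n_other_short = sum(
            1
            for r in catalog
            if r.size_class == "short" and r.intron_id not in flexi_ids
        )
        if flexi_profiles and other_short:
            # group totals count every intron in the group, with or without sites
            table = stats.binding_abundance_table(
                flexi_profiles,
                other_short,
                total_a=len(flexi_ids),
                total_b=n_other_short,
            )
            enr = stats.fisher_bh(
                table, alpha=config.alpha, min_pct=config.min_pct_class
            )
            _write("enrichment_flexi_vs_other_short.tsv", enr)
        if len(ranked) >= 2:
            matrix = cluster.build_keycode_matrix(
                flexi_profiles,
                list(ranked["rbp"]),
                alpha=config.alpha,
                min_pct=config.min_pct_subset,
            )
            if len(matrix) >= 2:
                matrix.to_csv(outdir / "keycode_matrix.tsv", sep="\t")
                outputs["keycode_matrix.tsv"] = outdir / "keycode_matrix.tsv"
                assignment = cluster.cluster_keycode_matrix(
                    matrix, k=config.n_clusters
                )
                memb = pd.DataFrame(
                    sorted(assignment.clusters.items()), columns=["rbp", "cluster"]
                )
                _write("rbp_clusters.tsv", memb)
                (outdir / "dendrogram.nwk").write_text(
                    cluster.linkage_to_newick(assignment) + "\n"
                )
                outputs["dendrogram.nwk"] = outdir / "dendrogram.nwk"
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e)

    # -------------------------------------------------------------- copies
    try:
        if config.standards:
            std = pd.read_csv(config.standards, sep="\t")
            model = quantify.fit_copy_number_model(
                list(std.itertuples(index=False, name=None))
            )
            rows = []
            for c in calls.values():
                if c.rpm > 0:
                    est, lo, hi = model.predict(c.rpm)
                    rows.append(
                        {
                            "intron_id": c.intron_id,
                            "rpm": c.rpm,
                            "copies_per_cell": est,
                            "low95": lo,
                            "high95": hi,
                        }
                    )
            _write("copies_per_cell.tsv", pd.DataFrame(rows))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("quantify", e)

    from flexiscan import __version__

    manifest = {
        "flexiscan_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "short_threshold": config.short_threshold,
            "end_window": config.end_window,
            "min_flexis": config.min_flexis,
            "alpha": config.alpha,
            "min_pct_class": config.min_pct_class,
            "min_pct_subset": config.min_pct_subset,
            "fc_threshold": config.fc_threshold,
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline wrote %d outputs to %s", len(outputs), outdir)
    return manifest
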