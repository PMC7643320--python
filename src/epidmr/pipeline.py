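"""End-to-end driver: simulate → count → test → calldmr → context → compare →
pathology, with a JSON manifest for reproducibility.

All randomness flows from the single config seed; rerunning with the same
configuration reproduces byte-identical outputs. The compare stage of a
single-run pipeline is a self-comparison: the strict-threshold DMR set against
the same comparison's relaxed-threshold set (the expected-100% diagonal) plus
PCA of RPKM at DMR windows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import DMRSet, extended_overlap, group_silhouette, pca_rpkm
from .context import (
    associate_genes,
    cpg_density_histogram,
    find_dmr_clusters,
    length_histogram,
    read_gene_annotation,
)
from .counts import rpkm_matrix, tmm_factors
from .diffmeth import estimate_common_dispersion, test_all_windows
from .dmr import assemble_dmrs, classify_direction, threshold_sweep
from .errors import ConfigurationError
from .io import (
    dmr_bed_frame,
    write_bed,
    write_counts_tsv,
    write_groups_tsv,
    write_results_tsv,
    write_truth_bed,
)
from .pathology import incidence_summary, load_f3_disease_table
from .simulate import SimulationConfig, simulate_dataset


@dataclass
class RunConfig:
    """Parameters of a full synthetic pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed_threshold: float = 1e-4
    extend_threshold: float = 0.1
    reach: int = 1000
    relaxed_threshold: float = 0.05
    min_mean_count: float = 1.0
    sweep_thresholds: tuple[float, ...] = tuple(
        10.0 ** -k for k in range(2, 8)
    )
    norm: str = "tmm"  # or "total-count"
    annotation: str = "synthetic"  # path to BED/GTF, or "synthetic"
    gene_distance: int = 10_000

    def validate(self) -> None:
        for thr in (
            self.seed_threshold,
            self.extend_threshold,
            self.relaxed_threshold,
            *self.sweep_thresholds,
        ):
            if not 0 < thr <= 1:
                raise ConfigurationError(f"threshold {thr} outside (0, 1]")
        if self.norm not in {"tmm", "total-count"}:
            raise ConfigurationError(f"unknown norm {self.norm!r}")
        if self.annotation != "synthetic" and not Path(self.annotation).exists():
            raise ConfigurationError(
                f"annotation file not found: {self.annotation}"
            )


def config_from_yaml(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**raw.pop("simulation", {}))
    if "sweep_thresholds" in raw:
        raw["sweep_thresholds"] = tuple(raw["sweep_thresholds"])
    return RunConfig(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _synthetic_annotation(genome, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic gene annotation over the synthetic genome: ~1 gene per
    20 windows, bodies 2–10 kb."""
    rows = []
    gene_i = 0
    for chrom, length in genome.chrom_lengths.items():
        pos = 0
        while pos < length - 10_000:
            pos += int(rng.integers(5_000, 30_000))
            body = int(rng.integers(2_000, 10_000))
            if pos + body >= length:
                break
            gene_i += 1
            rows.append(
                {
                    "gene": f"g{gene_i}",
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + body,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            pos += body
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            **asdict(config),
            "simulation": asdict(config.simulation),
        },
        "stages": {},
    }
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        # 1. simulate
        genome, truth, matrix = simulate_dataset(config.simulation)
        write_counts_tsv(matrix, outdir / "counts.tsv")
        write_groups_tsv(matrix, outdir / "groups.tsv")
        write_truth_bed(truth, outdir / "truth.bed")
        manifest["stages"]["simulate"] = {
            "n_windows": matrix.n_windows,
            "n_samples": matrix.n_samples,
            "n_planted": len(truth.regions),
        }

        # 2. count/normalize
        if config.norm == "tmm":
            matrix.norm_factors = tmm_factors(matrix)
        factors = pd.DataFrame(
            {"sample": matrix.samples, "factor": matrix.norm_factors}
        )
        factors.to_csv(outdir / "factors.tsv", sep="\t", index=False)
        manifest["stages"]["count"] = {
            "norm": config.norm,
            "library_sizes": [int(x) for x in matrix.library_sizes],
        }

        # 3. test
        disp = estimate_common_dispersion(matrix, config.min_mean_count)
        results = test_all_windows(matrix, disp, config.min_mean_count)
        write_results_tsv(results, outdir / "windows.tsv")
        manifest["stages"]["test"] = {
            "dispersion": disp.common_dispersion,
            "n_tested": int(results["tested"].sum()),
        }

        # 4. calldmr
        dmrs = assemble_dmrs(
            results,
            config.seed_threshold,
            config.extend_threshold,
            config.reach,
            genome=genome,
        )
        write_results_tsv(dmrs.drop(columns=[], errors="ignore"),
                          outdir / "dmrs.tsv")
        write_bed(dmr_bed_frame(dmrs), outdir / "dmrs.bed")
        sweep = threshold_sweep(
            results,
            list(config.sweep_thresholds),
            config.extend_threshold,
            config.reach,
        )
        sweep.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        _, hyper_fraction = classify_direction(dmrs)
        manifest["stages"]["calldmr"] = {
            "n_dmrs": len(dmrs),
            "n_multiple_window": int(
                (dmrs["n_significant_windows"] >= 2).sum()
            )
            if len(dmrs)
            else 0,
            "hyper_fraction": hyper_fraction,
        }

        # 5. context
        if config.annotation == "synthetic":
            ann_rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.simulation.seed, 1]
                )
            )
            annotation = _synthetic_annotation(genome, ann_rng)
        else:
            annotation = read_gene_annotation(config.annotation)
        associated = associate_genes(dmrs, annotation, config.gene_distance)
        assoc_out = associated.copy()
        assoc_out["genes"] = assoc_out["genes"].map(
            lambda g: ",".join(g)
        ) if len(assoc_out) else assoc_out.get("genes", [])
        write_results_tsv(assoc_out, outdir / "dmr_genes.tsv")
        cpg_hist = cpg_density_histogram(dmrs)
        len_hist = length_histogram(dmrs)
        cpg_hist.to_csv(outdir / "cpg_density_hist.tsv", sep="\t")
        len_hist.to_csv(outdir / "length_hist.tsv", sep="\t")
        clusters = find_dmr_clusters(dmrs)
        clusters_out = clusters.copy()
        if len(clusters_out):
            clusters_out["members"] = clusters_out["members"].map(
                lambda m: ",".join(m)
            )
        clusters_out.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        manifest["stages"]["context"] = {
            "n_genes_annotation": len(annotation),
            "n_dmrs_with_genes": int(
                (associated["genes"].map(len) > 0).sum()
            )
            if len(associated)
            else 0,
            "n_clusters": len(clusters),
        }

        # 6. compare (self-comparison + PCA)
        strict = DMRSet(
            "strict",
            dmrs[["chrom", "start", "end"]],
            config.seed_threshold,
        )
        relaxed_dmrs = assemble_dmrs(
            results,
            config.relaxed_threshold,
            config.extend_threshold,
            config.reach,
        )
        relaxed = DMRSet(
            "relaxed",
            relaxed_dmrs[["chrom", "start", "end"]]
            if len(relaxed_dmrs)
            else pd.DataFrame(columns=["chrom", "start", "end"]),
            config.relaxed_threshold,
        )
        ext = extended_overlap(strict, relaxed)
        silhouette = None
        if len(dmrs) >= 2:
            rpkm = rpkm_matrix(matrix)
            window_in_dmr = np.zeros(matrix.n_windows, dtype=bool)
            for _, reg in dmrs.iterrows():
                inside = (
                    (matrix.windows["chrom"] == reg["chrom"])
                    & (matrix.windows["start"] >= reg["start"])
                    & (matrix.windows["end"] <= reg["end"])
                )
                window_in_dmr |= inside.to_numpy()
            coords, var_explained = pca_rpkm(
                rpkm[window_in_dmr], matrix.groups
            )
            coords.insert(0, "sample", matrix.samples)
            coords.to_csv(outdir / "pca.tsv", sep="\t", index=False)
            silhouette = group_silhouette(coords)
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(ext, fh, indent=1)
        manifest["stages"]["compare"] = {
            "self_extended_overlap_percent": ext["percent"],
            "pca_silhouette": silhouette,
        }

        # 7. pathology (packaged disease table)
        table = load_f3_disease_table()
        incidence = incidence_summary(table)
        incidence.to_csv(outdir / "incidence.tsv", sep="\t", index=False)
        manifest["stages"]["pathology"] = {
            "n_animals": len(table),
            "incidence": {
                r["pathology"]: f"{r['n_positive']}/{r['n_evaluable']}"
                for _, r in incidence.iterrows()
            },
        }
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
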