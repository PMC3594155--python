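"""End-to-end pipeline orchestration.

Stages are executed in their fixed dependency order
(``simulate -> filter -> matrix -> normalize -> stats -> transloc ->
network``); each stage reads the plain-text artifacts of its predecessors
from the output directory and writes its own, and a ``manifest.json`` with
SHA-256 checksums of every input and output makes reruns verifiable:
unchanged inputs reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import matrix_stats, networks, normalization, synthetic, translocation
from .genome import Genome
from .matrix import bin_contacts, read_matrix_tsv, write_matrix_tsv
from .pair_filtering import (FilterPolicy, filter_pair_stream, read_contacts_frame,
                             read_pair_table, write_contacts)

STAGE_ORDER = ("simulate", "filter", "matrix", "normalize", "stats",
               "transloc", "network")


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str, what: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r} requires missing {what}: {path}")
    return path


def run_pipeline(config: Mapping, base_dir: Optional[Path] = None) -> dict:
    """Run the requested stages and return the artifact manifest.

    ``config`` keys: ``out_dir``, ``stages`` (subset of the stage order),
    ``seed``, per-stage parameter mappings (``simulate``, ``filter``,
    ``matrix``, ``normalize``, ``stats``, ``transloc``, ``network``) and,
    when the simulate stage is not run, an ``inputs`` mapping with ``pairs``,
    ``genome`` and optionally ``features`` paths.
    """
    config = dict(config)
    base = Path(base_dir) if base_dir is not None else Path(".")
    out_dir = base / config.get("out_dir", "out")
    out_dir.mkdir(parents=True, exist_ok=True)
    requested = list(config.get("stages", STAGE_ORDER))
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in requested]
    seed = int(config.get("seed", 0))
    outputs: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path):
        outputs.setdefault(stage, []).extend(str(p.relative_to(out_dir)) for p in paths)

    inputs = dict(config.get("inputs", {}))

    if "simulate" in stages:
        sim_cfg = dict(config.get("simulate", {}))
        sim_cfg.setdefault("seed", seed)
        if "translocation" in sim_cfg and sim_cfg["translocation"] is not None:
            sim_cfg["translocation"] = synthetic.TranslocationSpec(
                **dict(sim_cfg["translocation"]))
        params = synthetic.SimulationParams(**sim_cfg)
        synthetic.simulate_dataset(params, out_dir)
        record("simulate", out_dir / "genome.tsv", out_dir / "features.tsv",
               out_dir / "pairs.tsv", out_dir / "truth.json")
        inputs.setdefault("pairs", str(out_dir / "pairs.tsv"))
        inputs.setdefault("genome", str(out_dir / "genome.tsv"))
        inputs.setdefault("features", str(out_dir / "features.tsv"))

    genome: Optional[Genome] = None
    if set(stages) - {"simulate"}:
        genome_path = _require(Path(base / inputs.get("genome", "")),
                               stages[0], "genome table") \
            if "genome" in inputs else None
        if genome_path is None:
            raise PipelineError("no genome table available (run simulate or set inputs.genome)")
        genome = Genome.from_tsv(genome_path)

    if "filter" in stages:
        pairs_path = _require(Path(base / inputs.get("pairs", out_dir / "pairs.tsv")),
                              "filter", "read-pair table")
        policy = FilterPolicy(**config.get("filter", {}))
        contacts, stats = filter_pair_stream(read_pair_table(pairs_path),
                                             policy, genome)
        write_contacts(contacts, out_dir / "contacts.tsv")
        with open(out_dir / "filter_stats.json", "w") as fh:
            json.dump({"policy": dataclasses.asdict(policy), "stats": stats},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        record("filter", out_dir / "contacts.tsv", out_dir / "filter_stats.json")

    def contacts_df():
        path = _require(out_dir / "contacts.tsv", "matrix", "contacts file")
        return read_contacts_frame(path)

    resolution = int(config.get("matrix", {}).get("resolution", 500_000))
    if "matrix" in stages:
        df = contacts_df()
        paths = []
        for chrom in genome:
            m = bin_contacts(df, genome.grid(chrom, resolution))
            p = out_dir / f"matrix_{chrom}.tsv"
            write_matrix_tsv(m, p)
            paths.append(p)
        for ca, cb in genome.pairs():
            m = bin_contacts(df, genome.grid(ca, resolution),
                             genome.grid(cb, resolution))
            p = out_dir / f"matrix_{ca}__{cb}.tsv"
            write_matrix_tsv(m, p)
            paths.append(p)
        record("matrix", *paths)

    norm_cfg = dict(config.get("normalize", {}))
    norm_method = norm_cfg.pop("method", "dist-scn")
    if "normalize" in stages:
        params = normalization.NormalizationParams(
            **{k: v for k, v in norm_cfg.items()
               if k in ("euclid_threshold", "scn_tolerance", "scn_max_iter")})
        paths = []
        for chrom in genome:
            raw = read_matrix_tsv(_require(out_dir / f"matrix_{chrom}.tsv",
                                           "normalize", "contact matrix"))
            filtered = normalization.filter_low_coverage_bins(
                raw, params.euclid_threshold)
            if norm_method == "scn":
                norm = normalization.scn_normalize(filtered, params)
            elif norm_method == "dist-scn":
                norm = normalization.distance_scn_normalize(filtered, params)
            elif norm_method in normalization.SIMPLE_METHODS:
                norm = filtered.with_values(
                    normalization.simple_normalize(filtered, norm_method),
                    kind="simple")
            else:
                raise PipelineError(f"unknown normalization method {norm_method!r}")
            p = out_dir / f"norm_{chrom}.tsv"
            write_matrix_tsv(norm, p)
            paths.append(p)
            if (out_dir / f"norm_{chrom}.tsv.removed").exists():
                paths.append(out_dir / f"norm_{chrom}.tsv.removed")
        record("normalize", *paths)

    if "stats" in stages:
        paths = []
        for chrom in genome:
            source = out_dir / f"norm_{chrom}.tsv"
            if not source.exists():
                source = _require(out_dir / f"matrix_{chrom}.tsv", "stats",
                                  "contact matrix")
            m = read_matrix_tsv(source)
            corr = matrix_stats.correlation_matrix(m)
            p = out_dir / f"correlation_{chrom}.tsv"
            write_matrix_tsv(m.with_values(corr.values, kind="correlation"), p)
            paths.append(p)
            raw = read_matrix_tsv(_require(out_dir / f"matrix_{chrom}.tsv",
                                           "stats", "raw contact matrix"))
            sig = matrix_stats.poisson_significance(raw)
            p = out_dir / f"significance_{chrom}.tsv"
            write_matrix_tsv(raw.with_values(sig.pvalues, kind="significance"), p)
            paths.append(p)
        if len(genome) >= 2:
            df = contacts_df()
            profile = matrix_stats.observed_expected_ratios(
                matrix_stats.inter_pair_counts(df, genome))
            p = out_dir / "oe_ratio.tsv"
            profile.ratio_frame().to_csv(p, sep="\t", lineterminator="\n")
            paths.append(p)
        record("stats", *paths)

    if "transloc" in stages:
        t_cfg = dict(config.get("transloc", {}))
        chrom_a = t_cfg.get("chrom_a") or genome.chromosomes[0]
        chrom_b = t_cfg.get("chrom_b") or genome.chromosomes[1]
        df = contacts_df()
        model = translocation.detect_translocation(
            df, genome, chrom_a, chrom_b,
            resolutions=tuple(t_cfg.get("resolutions", (1_000_000, 100_000, 10_000))),
            enrichment_min=float(t_cfg.get("enrichment_min", 5.0)))
        paths = []
        p = out_dir / "translocation.tsv"
        if model is None:
            p.write_text("# no translocation detected\n")
        else:
            model.to_tsv(p)
            grid_a = genome.grid(model.chrom_a, resolution)
            grid_b = genome.grid(model.chrom_b, resolution)
            inter = bin_contacts(df, grid_a, grid_b)
            part = translocation.partition_regions(model, grid_a, grid_b)
            corrected = translocation.reconstruct_corrected_matrix(inter, part)
            pc = out_dir / f"corrected_{model.chrom_a}__{model.chrom_b}.tsv"
            write_matrix_tsv(corrected, pc)
            paths.append(pc)
        paths.append(p)
        record("transloc", *paths)

    if "network" in stages:
        n_cfg = dict(config.get("network", {}))
        features_path = _require(Path(base / inputs.get("features", "")),
                                 "network", "feature annotations")
        features = networks.read_features(features_path)
        node_kinds = n_cfg.get("node_kinds", ["GENE"])
        threshold = int(n_cfg.get("threshold", 0))
        df = contacts_df()
        counts = networks.map_contacts_to_features(df, features, node_kinds)
        g = networks.build_network(counts, threshold,
                                   kinds=networks.feature_kinds(features))
        pe = out_dir / "network_edges.tsv"
        networks.write_edge_list(g, pe)
        pm = out_dir / "network_node_metrics.tsv"
        networks.node_metrics_table(g).to_csv(pm, sep="\t", index=False,
                                              lineterminator="\n")
        record("network", pe, pm)

    checksums = {}
    for stage_files in outputs.values():
        for rel in stage_files:
            checksums[rel] = _sha256(out_dir / rel)
    input_checksums = {name: _sha256(Path(base / p)) for name, p in inputs.items()
                       if Path(base / p).exists()}
    manifest = {"config": _jsonable(config), "stages": outputs,
                "outputs": checksums, "inputs": input_checksums}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
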