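"""End-to-end orchestration with provenance capture.

The two entry points compose the library stages in their natural order:

* :func:`run_divergence_pipeline` — curation (optional) -> gappy-column
  trimming -> stretch mapping -> per-subset entropy profiles -> per-clade
  unique-residue tables.
* :func:`run_interface_pipeline` — contact extraction -> stretch grouping
  (optional, needs domain boundaries) -> buried surface area.

Every output directory receives a ``manifest.json`` naming the parameters,
the sha256 digest of each input file and the package version.  Reruns with
identical inputs and configuration are byte-identical: nothing here is
time-stamped and all randomness is seeded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .conservation import DEFAULT_ENTROPY_THRESHOLD, entropy_profile
from .curation import (
    CladePartition,
    CurationParams,
    deduplicate,
    extract_clades,
    filter_full_length,
    read_reference_map,
)
from .divergence import DivergenceParams, iterate_unique_calls
from .interface import (
    InterfaceParams,
    derive_stretches,
    find_interface_residues,
    buried_surface_area,
    stretches_frame,
)
from .io_formats import Alignment, read_alignment, read_newick, read_structure, write_fasta
from .msa import (
    DEFAULT_GAP_THRESHOLD,
    DIMERIZATION_STRETCHES,
    column_frequencies,
    consensus_pattern,
    map_reference_ranges,
    trim_gappy_columns,
)

logger = logging.getLogger("cladeface")


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class DivergenceConfig:
    """Inputs and parameters of the sequence half of the pipeline."""

    alignment_path: Path
    out_dir: Path
    clades_path: Path | None = None  # (clade, id) TSV; empty clade = unassigned
    tree_path: Path | None = None
    reference_map_path: Path | None = None  # (clade, id) TSV of reference leaves
    reference_id: str | None = None  # row used to map stretch coordinates
    stretch_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DIMERIZATION_STRETCHES)
    )
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD
    clade_set: tuple[str, ...] | None = None  # default: all clades
    freq_cutoff: float = 0.8
    ratio_cutoff: float = 50.0
    curation: CurationParams = field(default_factory=CurationParams)
    run_curation: bool = False


@dataclass
class InterfaceConfig:
    structure_path: Path
    out_dir: Path
    chain_a: str = "A"
    chain_b: str = "B"
    params: InterfaceParams = field(default_factory=InterfaceParams)
    domain_boundaries_path: Path | None = None  # (chain, domain, start, end) TSV
    include_ligands: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                raise PipelineError(f"stage {name}: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def read_clade_partition(path: Path, all_ids: Sequence[str]) -> CladePartition:
    """Load a (clade, id) TSV into a partition over ``all_ids``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    clades: dict[str, set[str]] = {}
    listed: set[str] = set()
    for clade, sid in zip(df["clade"], df["id"]):
        listed.add(sid)
        if clade:
            clades.setdefault(clade, set()).add(sid)
    unassigned = (set(all_ids) - set().union(*clades.values())) if clades else set(all_ids)
    return CladePartition(
        clades={k: frozenset(v) for k, v in clades.items()},
        unassigned=frozenset(unassigned),
    )


def read_domain_boundaries(path: Path) -> dict[str, dict[str, tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "domain": str,
                                            "start": int, "end": int})
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.chain), {})[str(r.domain)] = (int(r.start), int(r.end))
    return out


def _write_manifest(out_dir: Path, params: dict, inputs: Mapping[str, Path]) -> None:
    manifest = {
        "tool": "cladeface",
        "version": __version__,
        "parameters": params,
        "input_digests": {
            name: _sha256(Path(p)) for name, p in inputs.items() if p is not None
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_divergence_pipeline(config: DivergenceConfig) -> dict[str, Path]:
    """Run curation (optional), trimming, mapping, entropy and ratio stages.

    Returns a map of output names to paths.  Partial outputs from completed
    stages are retained on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    inputs: dict[str, Path] = {"alignment": config.alignment_path}

    with _stage("load_alignment"):
        alignment = read_alignment(config.alignment_path)

    partition: CladePartition | None = None
    if config.run_curation:
        with _stage("curation"):
            raw = alignment.records
            ungapped_ok = filter_full_length(
                raw, config.curation.full_length_min, config.curation.full_length_max
            )
            deduped, dup_map = deduplicate(ungapped_ok)
            kept_ids = {rec.id for rec in deduped}
            report = pd.DataFrame(
                [
                    {
                        "id": rec.id,
                        "ungapped_length": rec.length,
                        "kept": "yes" if rec.id in kept_ids else "no",
                        "reason": (
                            ""
                            if rec.id in kept_ids
                            else (
                                "duplicate"
                                if any(rec.id in v for v in dup_map.values())
                                else "length_out_of_range"
                            )
                        ),
                    }
                    for rec in raw
                ]
            )
            p = out / "curation_report.tsv"
            report.to_csv(p, sep="\t", index=False)
            outputs["curation_report"] = p
            alignment = Alignment(deduped)

    if config.clades_path is not None:
        with _stage("load_clades"):
            inputs["clades"] = config.clades_path
            partition = read_clade_partition(config.clades_path, alignment.ids)
    elif config.tree_path is not None:
        with _stage("clade_extraction"):
            if config.reference_map_path is None:
                raise ValueError("clade extraction requested but no reference map given")
            inputs["tree"] = config.tree_path
            inputs["reference_map"] = config.reference_map_path
            tree = read_newick(config.tree_path)
            refs = read_reference_map(config.reference_map_path)
            partition = extract_clades(
                tree, refs, config.curation.support_threshold
            )
            p = out / "clades.tsv"
            partition.to_frame().to_csv(p, sep="\t", index=False)
            outputs["clades"] = p

    with _stage("trim"):
        trimmed, column_index_map = trim_gappy_columns(
            alignment, config.gap_threshold
        )
        p = out / "trimmed_alignment.fasta"
        write_fasta(trimmed.records, p)
        outputs["trimmed_alignment"] = p

    annotations = None
    if config.reference_id is not None:
        with _stage("stretch_map"):
            annotations = map_reference_ranges(
                alignment,
                config.reference_id,
                config.stretch_ranges,
                column_index_map=column_index_map,
            )
            rows = []
            for ann in annotations:
                for offset, col in enumerate(ann.columns):
                    rows.append(
                        {
                            "stretch": ann.name,
                            "reference_residue": ann.reference_range[0] + offset,
                            "column": col,
                            "original_column": column_index_map[col - 1],
                        }
                    )
                for residue, orig in ann.missing:
                    rows.append(
                        {
                            "stretch": ann.name,
                            "reference_residue": residue,
                            "column": "",
                            "original_column": orig,
                        }
                    )
            p = out / "stretch_map.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            outputs["stretch_map"] = p

    with _stage("entropy"):
        subsets: dict[str, Sequence[str] | None] = {"all": None}
        if partition is not None:
            for clade, members in partition.clades.items():
                subsets[clade] = sorted(members)
        for label, subset in subsets.items():
            profile = entropy_profile(
                trimmed,
                subset=subset,
                threshold=config.entropy_threshold,
                columns=column_index_map,
            )
            p = out / f"entropy_{label}.tsv"
            profile.to_frame().to_csv(p, sep="\t", index=False)
            outputs[f"entropy_{label}"] = p
        table = column_frequencies(trimmed, columns=column_index_map)
        _, logo = consensus_pattern(table)
        p = out / "consensus_logo.tsv"
        logo.to_csv(p, sep="\t", index=False)
        outputs["consensus_logo"] = p

    if partition is not None and len(partition.clades) >= 2:
        with _stage("unique_residues"):
            clade_set = config.clade_set or tuple(sorted(partition.clades))
            params = DivergenceParams(
                clade_set=clade_set,
                freq_cutoff=config.freq_cutoff,
                ratio_cutoff=config.ratio_cutoff,
            )
            table = iterate_unique_calls(
                trimmed, partition, params, columns=column_index_map
            )
            # report in original column numbering; stretch annotation columns
            # are in the trimmed frame, so translate before intersecting
            frame = table.to_frame(annotations=None)
            if annotations is not None:
                trimmed_to_orig = {
                    i + 1: orig for i, orig in enumerate(column_index_map)
                }
                stretch_of = {}
                residue_of = {}
                for ann in annotations:
                    for offset, col in enumerate(ann.columns):
                        orig = trimmed_to_orig[col]
                        stretch_of[orig] = ann.name
                        residue_of[orig] = ann.reference_range[0] + offset
                frame["stretch"] = frame["column"].map(stretch_of).fillna("")
                frame["reference_residue"] = (
                    frame["column"].map(residue_of).fillna("").astype(object)
                )
            p = out / "unique_residues.tsv"
            frame.to_csv(p, sep="\t", index=False)
            outputs["unique_residues"] = p
            if annotations is not None:
                counts = {
                    clade: len(cols)
                    for clade, cols in table.unique_in_stretches(annotations).items()
                }
                p = out / "stretch_unique_counts.tsv"
                pd.DataFrame(
                    [{"clade": c, "unique_in_stretches": n} for c, n in counts.items()]
                ).to_csv(p, sep="\t", index=False)
                outputs["stretch_unique_counts"] = p

    _write_manifest(
        out,
        params={
            "gap_threshold": config.gap_threshold,
            "entropy_threshold": config.entropy_threshold,
            "freq_cutoff": config.freq_cutoff,
            "ratio_cutoff": config.ratio_cutoff,
            "clade_set": list(config.clade_set) if config.clade_set else None,
            "support_threshold": config.curation.support_threshold,
            "reference_id": config.reference_id,
            "stretch_ranges": {k: list(v) for k, v in config.stretch_ranges.items()},
            "run_curation": config.run_curation,
        },
        inputs=inputs,
    )
    outputs["manifest"] = out / "manifest.json"
    return outputs


def run_interface_pipeline(config: InterfaceConfig) -> dict[str, Path]:
    """Run contact extraction, stretch grouping and BSA on a dimer."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    inputs: dict[str, Path] = {"structure": config.structure_path}

    with _stage("load_structure"):
        structure = read_structure(
            config.structure_path, include_ligands=config.include_ligands
        )

    with _stage("contacts"):
        pairs, residues = find_interface_residues(
            structure,
            config.chain_a,
            config.chain_b,
            cutoff=config.params.distance_cutoff,
        )
        rows = [
            {
                "residue_a": p.residue_a,
                "residue_b": p.residue_b,
                "min_distance_A": f"{p.distance:.3f}",
            }
            for p in pairs
        ]
        p = out / "contacts.tsv"
        pd.DataFrame(rows, columns=["residue_a", "residue_b", "min_distance_A"]).to_csv(
            p, sep="\t", index=False
        )
        outputs["contacts"] = p

    if config.domain_boundaries_path is not None:
        with _stage("stretches"):
            inputs["domain_boundaries"] = config.domain_boundaries_path
            boundaries = read_domain_boundaries(config.domain_boundaries_path)
            stretches = derive_stretches(
                pairs, boundaries, config.chain_a, config.chain_b
            )
            p = out / "stretches.tsv"
            stretches_frame(stretches).to_csv(p, sep="\t", index=False)
            outputs["stretches"] = p
    else:
        logger.warning("no domain boundaries given; skipping stretch grouping")

    with _stage("bsa"):
        per_protomer, total = buried_surface_area(
            structure, config.chain_a, config.chain_b, config.params
        )
        rows = [
            {"protomer": cid, "bsa_A2": f"{area:.1f}"}
            for cid, area in per_protomer.items()
        ] + [{"protomer": "total", "bsa_A2": f"{total:.1f}"}]
        p = out / "bsa.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        outputs["bsa"] = p

    _write_manifest(
        out,
        params={
            "distance_cutoff": config.params.distance_cutoff,
            "probe_radius": config.params.probe_radius,
            "sphere_points": config.params.sphere_points,
            "chains": [config.chain_a, config.chain_b],
            "include_ligands": config.include_ligands,
        },
        inputs=inputs,
    )
    outputs["manifest"] = out / "manifest.json"
    return outputs


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
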