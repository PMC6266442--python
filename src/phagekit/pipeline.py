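"""Pipeline orchestration: annotate → features → compare, plus phenotype runs.

Each run writes its outputs plus a machine-readable ``manifest.json``
(inputs, parameters, package version) so reruns are reproducible; outputs
are byte-identical under a fixed seed and configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .compare import best_hits, genome_map_table, shared_proteins_at_cutoff
from .genome import FeatureTable, GenomeRecord, gc_content, read_fasta, write_feature_table
from .orfs import SDParams, annotate_genome, start_codon_usage
from .phenotype import (
    count_infected,
    estimate_burst,
    one_way_anova,
    read_growth_csv,
    read_spot_csv,
    tukey_hsd,
)
from .proteins import ProteinRecord, translate

__all__ = ["ConfigError", "DataError", "run_annotate", "run_compare", "run_phenotype"]


class ConfigError(ValueError):
    """Bad or missing configuration (e.g. a path that does not exist)."""


class DataError(ValueError):
    """Well-configured run with unusable data."""


def _require_file(path, what: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"{what} not found: {p}")
    return p


def _write_manifest(out_dir: Path, stage: str, inputs: dict, params: dict) -> None:
    manifest = {
        "stage": stage,
        "phagekit_version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _orf_proteins(g: GenomeRecord, orfs) -> list[ProteinRecord]:
    from Bio.Seq import Seq

    proteins = []
    for o in orfs:
        dna = g.sequence[o.start - 1 : o.end]
        if o.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        proteins.append(ProteinRecord(o.id or f"{o.start}..{o.end}", translate(dna)).with_features())
    return proteins


def run_annotate(
    fasta: str | Path,
    out_dir: str | Path,
    min_aa: int = 45,
    require_sd: bool = True,
    strands: str = "both",
    sd_params: SDParams = SDParams(),
) -> dict:
    """Annotate every genome in a FASTA file; emit TSV/GFF3/protein FASTA.

    Returns a per-genome report with ORF counts, start-codon usage and GC
    content; empty genomes produce valid empty outputs.
    """
    fasta = _require_file(fasta, "genome FASTA")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"genomes": {}}
    for g in read_fasta(fasta):
        orfs = annotate_genome(
            g, min_aa=min_aa, strands=strands, require_sd=require_sd, sd_params=sd_params
        )
        proteins = _orf_proteins(g, orfs)
        for o, p in zip(orfs, proteins):
            o.mw_kda, o.pi = p.mw_kda, p.pi
        table = FeatureTable(genome_id=g.id, rows=orfs)
        write_feature_table(table, out / f"{g.id}.tsv", format="tsv")
        write_feature_table(table, out / f"{g.id}.gff3", format="gff3")
        with open(out / f"{g.id}.faa", "w") as fh:
            for p in proteins:
                fh.write(f">{p.id}\n{p.sequence}\n")
        report["genomes"][g.id] = {
            "length_bp": g.length_bp,
            "gc_percent": gc_content(g) if g.length_bp else None,
            "orf_count": len(orfs),
            "start_codon_usage": start_codon_usage(orfs) if orfs else {},
        }
    _write_manifest(
        out, "annotate", {"fasta": fasta},
        {"min_aa": min_aa, "require_sd": require_sd, "strands": strands,
         "sd_params": asdict(sd_params)},
    )
    return report


def _read_protein_fasta(path: Path) -> list[ProteinRecord]:
    from Bio import SeqIO

    records = [ProteinRecord(r.id, str(r.seq).rstrip("*")) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise DataError(f"no protein records in {path}")
    return records


def run_compare(
    query_faa: str | Path,
    subject_faa: str | Path,
    out_dir: str | Path,
    cutoffs: tuple[float, ...] = (60, 70, 80, 90, 100),
    min_identity: float = 0.0,
    strict: bool = False,
) -> dict:
    """Best-hit comparison of two proteomes with per-cutoff shared counts."""
    query_faa = _require_file(query_faa, "query proteome FASTA")
    subject_faa = _require_file(subject_faa, "subject proteome FASTA")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qs = _read_protein_fasta(query_faa)
    ss = _read_protein_fasta(subject_faa)
    hits = best_hits(qs, ss, min_identity=min_identity)
    with open(out / "hits.tsv", "w") as fh:
        fh.write("query\tsubject\tidentical\tlen_q\tlen_s\tpct_identity\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identical_residues}\t"
                f"{h.query_len}\t{h.subject_len}\t{h.percent_identity}\n"
            )
    shared = {
        float(c): shared_proteins_at_cutoff(hits, c, strict=strict).count
        for c in sorted(cutoffs)
    }
    _write_manifest(
        out, "compare", {"query": query_faa, "subject": subject_faa},
        {"cutoffs": list(map(float, cutoffs)), "min_identity": min_identity,
         "strict": strict},
    )
    return {"n_hits": len(hits), "shared_at_cutoff": shared}


def run_compare_tables(tables, hits_by_pair, shade_cutoffs=(90.0, 80.0, 70.0)):
    """Genome-map layout over annotated feature tables (thin wrapper)."""
    return genome_map_table(tables, hits_by_pair, shade_cutoffs)


def run_phenotype(
    growth_csv: str | Path | None = None,
    spot_csv: str | Path | None = None,
    out_dir: str | Path | None = None,
    alpha: float = 0.01,
    endpoints: str = "plateau",
) -> dict:
    """Growth-curve estimates (+ ANOVA/Tukey across temperatures) and host range."""
    if growth_csv is None and spot_csv is None:
        raise ConfigError("provide a growth CSV, a spot CSV, or both")
    report: dict = {}
    if growth_csv is not None:
        curves = read_growth_csv(_require_file(growth_csv, "growth CSV"))
        per_temp = {}
        groups = []
        for c in curves:
            est = estimate_burst(c, endpoints=endpoints)
            per_temp[c.temperature_C] = {
                "burst_size": est.burst_size,
                "burst_sd": est.burst_sd,
                "latent_period_min": est.latent_period_min,
                "latent_sd": est.latent_sd,
            }
            # replicate-level burst sizes feed the between-temperature ANOVA
            reps = [
                estimate_burst(
                    type(c)(c.temperature_C, c.moi, c.times_min, rep[None, :]),
                    endpoints=endpoints,
                ).burst_size
                for rep in c.titers
            ]
            groups.append(reps)
        report["growth"] = {"per_temperature": per_temp}
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            f, p = one_way_anova(groups)
            report["growth"]["anova"] = {"F": f, "p": p}
            report["growth"]["tukey"] = tukey_hsd(groups, alpha=alpha).to_dict("records")
        else:
            report["growth"]["anova"] = "skipped: fewer than two replicated temperatures"
    if spot_csv is not None:
        records = read_spot_csv(_require_file(spot_csv, "spot CSV"))
        total, pathogenic, nonpath = count_infected(records)
        report["host_range"] = {
            "strains": len(records),
            "infected": total,
            "pathogenic_infected": pathogenic,
            "non_pathogenic_infected": nonpath,
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "phenotype_report.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n"
        )
        _write_manifest(
            out, "phenotype",
            {"growth_csv": growth_csv or "", "spot_csv": spot_csv or ""},
            {"alpha": alpha, "endpoints": endpoints},
        )
    return report
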