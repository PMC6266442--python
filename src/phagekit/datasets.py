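"""Bundled reference datasets: the ST32 phage feature table and host range.

Two small fixtures transcribed from the published characterization of
coliphage ST32 (GenBank MF044458.2): the 79-row ORF feature table (with SD
contexts, MW/pI, and best-hit identity figures against related phages,
chiefly phiEcoM-GJ1) and the 73-strain spot-test host-range matrix. The
genome sequence itself is not bundled; analyses that need it accept a
locally supplied FASTA.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import HomologyHit
from .genome import FeatureTable
from .orfs import OrfCandidate, start_codon_usage
from .phenotype import SpotTestRecord, count_infected
from ._round import round_half_up

__all__ = [
    "TRNA_ARG",
    "load_orf_table",
    "load_feature_table",
    "load_identity_hits",
    "load_host_range",
    "annotation_summary",
]

# The annotated tRNA-Arg gene interval (1-based inclusive, intron-free).
TRNA_ARG = ("tRNA-Arg", 15909, 16003)

GENOME_LENGTH_BP = 53092
GENOME_GC_PERCENT = 44.14


def _data_path(name: str):
    return resources.files("phagekit.data").joinpath(name)


def load_orf_table() -> pd.DataFrame:
    """The 79-row ORF feature table as a DataFrame."""
    with resources.as_file(_data_path("st32_orf_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["predicted_function"] = df["predicted_function"].fillna("")
    df["hit_subject"] = df["hit_subject"].fillna("")
    return df


def load_feature_table() -> FeatureTable:
    """The ORF table as a FeatureTable (plus the tRNA-Arg interval)."""
    df = load_orf_table()
    rows = [
        OrfCandidate(
            id=f"ORF{r.orf_id}",
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            start_codon=r.start_codon,
            sd_context=r.sd_context,
            mw_kda=float(r.mw_kda),
            pi=float(r.pi),
            predicted_function=r.predicted_function,
        )
        for r in df.itertuples()
    ]
    return FeatureTable(genome_id="ST32", rows=rows, extra_features=[TRNA_ARG])


def load_identity_hits() -> list[HomologyHit]:
    """Best-hit identity rows of the feature table as HomologyHits.

    ``reported_identity`` carries the printed percentage; the printed
    identical-residue count and smallest-protein length fill the numeric
    fields.
    """
    df = load_orf_table()
    hits = []
    for r in df.itertuples():
        if not r.hit_subject or pd.isna(r.hit_identical):
            continue
        smallest = int(r.hit_smallest)
        aligned = int(r.hit_aligned_len)
        hits.append(
            HomologyHit(
                query_id=f"ORF{r.orf_id}",
                subject_id=r.hit_subject,
                identical_residues=int(r.hit_identical),
                query_len=smallest,
                subject_len=max(smallest, aligned),
                reported_identity=int(r.hit_pct),
            )
        )
    return hits


def load_host_range() -> list[SpotTestRecord]:
    """The 73-strain spot-test matrix as scored records."""
    with resources.as_file(_data_path("st32_host_range.csv")) as p:
        df = pd.read_csv(p)
    return [
        SpotTestRecord.from_score(str(r.strain_id), bool(r.pathogenic), r.score)
        for r in df.itertuples()
    ]


def annotation_summary() -> dict:
    """Genome-annotation statistics recomputed from the bundled table."""
    df = load_orf_table()
    functional = int((df["predicted_function"] != "").sum())
    usage = start_codon_usage(list(df["start_codon"]))
    total, pathogenic, nonpath = count_infected(load_host_range())
    return {
        "orf_count": int(len(df)),
        "forward_strand_orfs": int((df["strand"] == "+").sum()),
        "functional_assignments": functional,
        "functional_pct": round_half_up(100.0 * functional / len(df), 1),
        "start_codon_usage": usage,
        "trna_length_bp": TRNA_ARG[2] - TRNA_ARG[1] + 1,
        "host_range": {
            "strains_tested": 73,
            "infected": total,
            "pathogenic_infected": pathogenic,
            "non_pathogenic_infected": nonpath,
        },
    }
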