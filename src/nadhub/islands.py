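"""PII-nadE genomic-island detection pipeline.

Conserved gene neighbourhood is a fingerprint of physical interaction between
the encoded proteins.  This pipeline detects co-localised PII and nadE
homolog genes across a genome set from precomputed homology hit tables:

1. keep one genome per species (type-strain > complete > chromosome >
   scaffold > contig, ties broken by accession);
2. call a "PII island" around every PII homolog hit with e-value <= 1e-5
   whose 10-kb up/downstream window fits entirely on its contig;
3. pair each nadE homolog hit encoded within an island with its closest PII
   gene on the same contig, keeping pairs with a gene-midpoint distance
   strictly below 2000 bp;
4. dereplicate the resulting pairs and roll their counts up by taxonomy.

Coordinates are 1-based inclusive (GFF3/BLAST convention); midpoints are
floor-rounded; distance is measured on nucleotide coordinates regardless of
strand.  The pipeline consumes hit tables rather than running a search
engine, so it is deterministic and download-free.

Canonical hit-table columns: query_id, genome, contig_id, start, end, strand,
evalue, bitscore, subject_protein_id.  A reader for BLAST outfmt-6 tables
plus a contig-to-genome map is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HIT_COLUMNS", "OUTFMT6_COLUMNS", "read_hits_outfmt6", "dedupe_genomes",
    "call_islands", "pair_nade_with_pii", "dereplicate", "taxonomy_rollup",
    "IslandPipelineResult", "run_pipeline",
]

HIT_COLUMNS = ["query_id", "genome", "contig_id", "start", "end", "strand",
               "evalue", "bitscore", "subject_protein_id"]

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                   "bitscore"]

_LEVEL_RANK = {"complete": 0, "chromosome": 1, "scaffold": 2, "contig": 3}


def read_hits_outfmt6(path, contig_to_genome: Mapping[str, str]) -> pd.DataFrame:
    """Load a BLAST tabular (outfmt 6) hit table into canonical layout.

    The subject (sseqid) is taken as the contig searched (tblastn-style);
    sstart > send encodes the minus strand.  ``contig_to_genome`` maps contig
    ids to genome accessions.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    start = df[["sstart", "send"]].min(axis=1)
    end = df[["sstart", "send"]].max(axis=1)
    return pd.DataFrame({
        "query_id": df["qseqid"],
        "genome": df["sseqid"].map(dict(contig_to_genome)),
        "contig_id": df["sseqid"],
        "start": start.astype(int),
        "end": end.astype(int),
        "strand": np.where(df["sstart"] <= df["send"], "+", "-"),
        "evalue": df["evalue"].astype(float),
        "bitscore": df["bitscore"].astype(float),
        "subject_protein_id": df["qseqid"].astype(str) + "@" + df["sseqid"].astype(str),
    })


def dedupe_genomes(metas: pd.DataFrame) -> pd.DataFrame:
    """Select exactly one genome per species.

    Priority: type strains first, then assembly level (complete > chromosome
    > scaffold > contig), ties broken by lexicographic assembly accession so
    the choice is deterministic.  Expects columns assembly_accession,
    species_taxid, assembly_level, refseq_category.
    """
    if metas.empty:
        return metas.copy()
    df = metas.copy()
    cat = df["refseq_category"].astype(str).str.lower()
    df["_is_type"] = ~(cat.str.contains("type") | cat.str.contains("reference"))
    df["_level"] = (df["assembly_level"].astype(str).str.lower()
                    .map(_LEVEL_RANK).fillna(len(_LEVEL_RANK)))
    df = df.sort_values(["species_taxid", "_is_type", "_level",
                         "assembly_accession"], kind="mergesort")
    out = df.drop_duplicates("species_taxid", keep="first")
    return out.drop(columns=["_is_type", "_level"]).reset_index(drop=True)


def call_islands(pii_hits: pd.DataFrame, contigs: Mapping[tuple[str, str], int] | pd.DataFrame,
                 flank: int = 10_000, evalue_max: float = 1e-5) -> pd.DataFrame:
    """Call PII islands: flanked windows around significant PII hits.

    A hit with evalue <= ``evalue_max`` (boundary inclusive) becomes an
    island spanning [start - flank, end + flank] if that window lies fully
    within its contig; hits on contigs too short for the window are discarded
    with a logged reason, as are hits above the e-value threshold.
    """
    if isinstance(contigs, pd.DataFrame):
        contigs = {(r.genome, r.contig_id): int(r.length)
                   for r in contigs.itertuples()}
    rows = []
    for hit in pii_hits.itertuples():
        key = (hit.genome, hit.contig_id)
        if key not in contigs:
            raise KeyError(f"hit references unknown contig {key}")
        if hit.evalue > evalue_max:
            logger.info("discard PII hit %s: evalue %.3g > %.3g",
                        hit.query_id, hit.evalue, evalue_max)
            continue
        w_start, w_end = hit.start - flank, hit.end + flank
        if w_start < 1 or w_end > contigs[key]:
            logger.info("discard PII hit %s on %s: %d-bp window truncated by "
                        "contig bounds", hit.query_id, hit.contig_id,
                        (hit.end - hit.start + 1) + 2 * flank)
            continue
        rows.append({
            "genome": hit.genome, "contig_id": hit.contig_id,
            "pii_start": int(hit.start), "pii_end": int(hit.end),
            "pii_midpoint": (int(hit.start) + int(hit.end)) // 2,
            "window_start": int(w_start), "window_end": int(w_end),
            "pii_protein_id": hit.subject_protein_id, "pii_evalue": hit.evalue,
        })
    cols = ["genome", "contig_id", "pii_start", "pii_end", "pii_midpoint",
            "window_start", "window_end", "pii_protein_id", "pii_evalue"]
    return pd.DataFrame(rows, columns=cols)


def pair_nade_with_pii(nade_hits: pd.DataFrame, islands: pd.DataFrame,
                       evalue_max: float = 1e-5, max_distance: int = 2000,
                       use_island_midpoint: bool = False) -> pd.DataFrame:
    """Pair nadE homolog hits with their closest PII neighbour.

    Only nadE hits with evalue <= ``evalue_max`` whose gene lies entirely
    within a PII-island window are considered (the "PII neighbours" set).
    The distance is between floor-rounded gene midpoints (or to the island
    window midpoint when ``use_island_midpoint``), strand-agnostic; pairs are
    kept when the distance is strictly below ``max_distance``.  A nadE hit
    equidistant between two islands ties to the lower-coordinate one.
    """
    rows = []
    for hit in nade_hits.itertuples():
        if hit.evalue > evalue_max:
            logger.info("discard nadE hit %s: evalue %.3g > %.3g",
                        hit.query_id, hit.evalue, evalue_max)
            continue
        cand = islands[(islands["genome"] == hit.genome)
                       & (islands["contig_id"] == hit.contig_id)
                       & (islands["window_start"] <= hit.start)
                       & (islands["window_end"] >= hit.end)]
        if cand.empty:
            logger.info("discard nadE hit %s: outside every PII island",
                        hit.query_id)
            continue
        nade_mid = (int(hit.start) + int(hit.end)) // 2
        if use_island_midpoint:
            ref = (cand["window_start"] + cand["window_end"]) // 2
        else:
            ref = cand["pii_midpoint"]
        dist = (ref - nade_mid).abs()
        # closest island; equidistant ties resolved to the lower coordinate
        best = cand.assign(_d=dist, _ref=ref).sort_values(
            ["_d", "_ref"], kind="mergesort").iloc[0]
        if best["_d"] >= max_distance:
            logger.info("discard nadE hit %s: midpoint distance %d >= %d",
                        hit.query_id, best["_d"], max_distance)
            continue
        rows.append({
            "genome": hit.genome, "contig_id": hit.contig_id,
            "nade_protein_id": hit.subject_protein_id,
            "nade_start": int(hit.start), "nade_end": int(hit.end),
            "nade_midpoint": nade_mid,
            "pii_protein_id": best["pii_protein_id"],
            "pii_midpoint": int(best["pii_midpoint"]),
            "midpoint_distance": int(best["_d"]),
            "nade_evalue": hit.evalue,
        })
    cols = ["genome", "contig_id", "nade_protein_id", "nade_start", "nade_end",
            "nade_midpoint", "pii_protein_id", "pii_midpoint",
            "midpoint_distance", "nade_evalue"]
    return pd.DataFrame(rows, columns=cols)


def dereplicate(pairs: pd.DataFrame,
                sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Remove duplicate nadE entries from the pair list.

    Duplicates are identified by identical protein sequence when
    ``sequences`` (protein_id -> sequence) is supplied, otherwise by
    nade_protein_id.  The first occurrence under a canonical sort by
    (genome, contig_id, nade_start, nade_protein_id) is kept; drops are
    logged.
    """
    if pairs.empty:
        return pairs.copy()
    df = pairs.sort_values(["genome", "contig_id", "nade_start",
                            "nade_protein_id"], kind="mergesort")
    if sequences is not None:
        key = df["nade_protein_id"].map(dict(sequences))
        missing = df["nade_protein_id"][key.isna()]
        if len(missing):
            raise KeyError(f"no sequence for {sorted(set(missing))[:5]} ...")
    else:
        key = df["nade_protein_id"]
    dup = key.duplicated(keep="first")
    for pid in df.loc[dup, "nade_protein_id"]:
        logger.info("dereplicate: dropping duplicate nadE entry %s", pid)
    return df.loc[~dup.to_numpy()].reset_index(drop=True)


def taxonomy_rollup(pairs: pd.DataFrame, lineages: pd.DataFrame,
                    genome_taxids: Mapping[str, int],
                    ranks: tuple[str, ...] = ("phylum", "class")) -> dict[str, pd.DataFrame]:
    """Count dereplicated pairs per taxonomic rank value.

    ``lineages`` is an NCBI-style taxid -> lineage table with a ``taxid``
    column plus one column per rank; genomes whose taxid is absent are
    counted as "unclassified".  Per rank the counts sum to the number of
    pairs.
    """
    lin = lineages.set_index("taxid")
    out = {}
    taxids = pairs["genome"].map(dict(genome_taxids))
    for rank in ranks:
        values = []
        for t in taxids:
            if pd.notna(t) and int(t) in lin.index:
                values.append(str(lin.loc[int(t), rank]))
            else:
                values.append("unclassified")
        counts = pd.Series(values, name="count").value_counts()
        out[rank] = counts.rename_axis(rank).reset_index()
    return out


@dataclass
class IslandPipelineResult:
    genomes: pd.DataFrame
    islands: pd.DataFrame
    pairs: pd.DataFrame
    rollup: dict[str, pd.DataFrame]


def run_pipeline(metas: pd.DataFrame, contigs: pd.DataFrame,
                 pii_hits: pd.DataFrame, nade_hits: pd.DataFrame,
                 lineages: pd.DataFrame | None = None,
                 genome_taxids: Mapping[str, int] | None = None,
                 flank: int = 10_000, evalue_max: float = 1e-5,
                 max_distance: int = 2000,
                 sequences: Mapping[str, str] | None = None,
                 use_island_midpoint: bool = False) -> IslandPipelineResult:
    """End-to-end pipeline: dedupe -> islands -> pairs -> dereplicate -> rollup."""
    genomes = dedupe_genomes(metas)
    keep = set(genomes["assembly_accession"])
    pii = pii_hits[pii_hits["genome"].isin(keep)]
    nade = nade_hits[nade_hits["genome"].isin(keep)]
    islands_df = call_islands(pii, contigs, flank=flank, evalue_max=evalue_max)
    pairs = pair_nade_with_pii(nade, islands_df, evalue_max=evalue_max,
                               max_distance=max_distance,
                               use_island_midpoint=use_island_midpoint)
    pairs = dereplicate(pairs, sequences=sequences)
    rollup = {}
    if lineages is not None and genome_taxids is not None:
        rollup = taxonomy_rollup(pairs, lineages, genome_taxids)
    return IslandPipelineResult(genomes, islands_df, pairs, rollup)
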