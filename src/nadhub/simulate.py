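"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed) and emits a
:class:`SyntheticTruth` alongside the dataset, so recovery tests can compare
pipeline output against the planted truth.  Substreams are derived from the
global seed as ``default_rng([seed, crc32(scenario_name)])``: adding a new
scenario never shifts the draws of existing ones.

What the generators emulate (and what they do not): dose-response and
sensorgram generators add multiplicative CV / additive Gaussian noise and
linear drift on top of the exact rate laws — they do not model pipetting
series correlation, substrate depletion or mass-transport artefacts.  The
genome generator emits coordinate-level hit tables with planted PII-nadE
pairs and a decoy for every discard rule — it does not emit nucleotide
sequence.  The protein-family generator applies iid point mutations — no
indels or selection.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bli, kinetics

__all__ = ["SyntheticTruth", "substream", "gen_dose_response",
           "gen_sensorgrams", "gen_genome_set", "GenomeSet",
           "gen_protein_families", "gen_lfq_table"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# default taxonomy mix: skewed toward the classes where PII-nadE islands
# are most often found
DEFAULT_TAXONOMY_MIX = {
    ("Proteobacteria", "Betaproteobacteria"): 0.40,
    ("Proteobacteria", "Gammaproteobacteria"): 0.25,
    ("Proteobacteria", "Alphaproteobacteria"): 0.15,
    ("Firmicutes", "Bacilli"): 0.12,
    ("Actinobacteria", "Actinomycetia"): 0.08,
}


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to every generated dataset."""

    scenario: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            raise TypeError(f"not serialisable: {type(o)}")
        text = json.dumps({"scenario": self.scenario, "seed": self.seed,
                           "params": self.params}, indent=2, default=default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def substream(seed: int | None, scenario: str) -> np.random.Generator:
    """Independent, reproducible random stream for one scenario."""
    tag = zlib.crc32(scenario.encode())
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([seed, tag])


def gen_dose_response(model: str, params: Mapping[str, float],
                      concentrations: Sequence[float], noise_cv: float = 0.03,
                      replicates: int = 3, seed: int | None = 0,
                      predictor: str | None = None,
                      ) -> tuple[kinetics.DoseResponseDataset, SyntheticTruth]:
    """Noisy dose-response data from a named rate law.

    Responses are ``model(c) * (1 + eps)`` with eps ~ Normal(0, noise_cv),
    mirroring triplicate activity assays with a constant coefficient of
    variation.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = kinetics.MODEL_SPECS[model] if isinstance(model, str) else model
    pred = predictor or spec.predictor_names[0]
    conc = np.repeat(np.asarray(list(concentrations), float), replicates)
    reps = np.tile(np.arange(replicates), len(list(concentrations)))
    clean = np.asarray(kinetics.evaluate_model(spec, params, {pred: conc}), float)
    rng = substream(seed, f"dose_response/{spec.model_id}")
    resp = clean * (1.0 + rng.normal(0.0, noise_cv, conc.size)) if noise_cv > 0 \
        else clean.copy()
    ds = kinetics.DoseResponseDataset(conc, resp, replicate_ids=reps,
                                      effector_name=pred)
    truth = SyntheticTruth("dose_response", seed, {
        "model": spec.model_id, "params": dict(params),
        "noise_cv": noise_cv, "replicates": replicates,
        "concentrations": list(map(float, concentrations)),
    })
    return ds, truth


def gen_sensorgrams(params: bli.BindingParams, concentrations: Sequence[float],
                    noise_sd: float = 0.02, drift: float = 0.0,
                    phase_times: Mapping[str, float] | None = None,
                    seed: int | None = 0, dt: float = 1.0,
                    ) -> tuple[list[bli.Sensorgram], SyntheticTruth]:
    """One simulated sensorgram per analyte concentration, one seed stream."""
    rng = substream(seed, "sensorgrams")
    out = []
    for c in concentrations:
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(bli.simulate_sensorgram(params, c, phase_times=phase_times,
                                           noise_sd=noise_sd, drift=drift,
                                           seed=sub, dt=dt))
    truth = SyntheticTruth("sensorgrams", seed, {
        "kON": params.kON, "kOFF": params.kOFF, "Rmax": params.Rmax,
        "Kd_M": params.Kd, "concentrations_nM": list(map(float, concentrations)),
        "noise_sd": noise_sd, "drift": drift,
    })
    return out, truth


@dataclass
class GenomeSet:
    """Synthetic genome-set inputs for the island pipeline, plus truth."""

    metas: pd.DataFrame
    contigs: pd.DataFrame
    pii_hits: pd.DataFrame
    nade_hits: pd.DataFrame
    lineages: pd.DataFrame
    genome_taxids: dict
    truth: SyntheticTruth

    def expected_pairs(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth.params["expected_pairs"])


def _hit(query, genome, contig, start, end, strand, evalue, pid):
    return {"query_id": query, "genome": genome, "contig_id": contig,
            "start": int(start), "end": int(end), "strand": strand,
            "evalue": float(evalue), "bitscore": 200.0,
            "subject_protein_id": pid}


def gen_genome_set(n_genomes: int = 50, p_pair: float = 0.6,
                   pair_distance_range: tuple[int, int] = (200, 1999),
                   decoy_distance_min: int = 3000,
                   contig_length_range: tuple[int, int] = (60_000, 120_000),
                   include_decoys: bool = True,
                   duplicate_species_fraction: float = 0.2,
                   taxonomy_mix: Mapping | None = None,
                   flank: int = 10_000,
                   seed: int | None = 0) -> GenomeSet:
    """Genome set with planted PII-nadE pairs and decoys for every filter.

    Each genome carries a PII hit whose island fits its contig; with
    probability ``p_pair`` a nadE hit is planted at a midpoint distance drawn
    from ``pair_distance_range`` (all below 2000 bp).  Decoys exercise every
    discard rule: a nadE hit at >= ``decoy_distance_min`` inside the island,
    a weak nadE hit (e-value 1e-4) next to the PII gene, a PII hit too close
    to the contig edge for its window, a weak PII hit, and a PII hit on a
    contig too short for the 20-kb window.  A fraction of species get a
    second, lower-priority assembly carrying its own planted pair, which the
    genome dedupe step must discard.  Truth lists the expected surviving
    pairs and the per-class counts.
    """
    if pair_distance_range[1] >= 2000:
        raise ValueError("pair distances must stay below 2000 bp")
    if decoy_distance_min < 2000:
        raise ValueError("decoy_distance_min must be >= 2000")
    if decoy_distance_min + 1000 > flank:
        raise ValueError("decoy distance must fit inside the island flank")
    rng = substream(seed, "genome_set")
    mix = dict(taxonomy_mix or DEFAULT_TAXONOMY_MIX)
    taxa = list(mix)
    weights = np.array([mix[t] for t in taxa], float)
    weights = weights / weights.sum()

    metas, contigs, pii_rows, nade_rows, lineage_rows = [], [], [], [], []
    genome_taxids, expected = {}, []
    pii_len, nade_len = 340, 2000

    for g in range(n_genomes):
        acc = f"GCF_{g:06d}.1"
        taxid = 1000 + g
        species = 5000 + g
        phylum, clazz = taxa[rng.choice(len(taxa), p=weights)]
        L = int(rng.integers(*contig_length_range))
        contig = f"{acc}_c1"
        metas.append({"assembly_accession": acc, "taxid": taxid,
                      "species_taxid": species, "assembly_level": "complete",
                      "refseq_category": "type strain",
                      "organism_name": f"Synthetica bacterium sp{g}"})
        contigs.append({"genome": acc, "contig_id": contig, "length": L})
        lineage_rows.append({"taxid": taxid, "phylum": phylum, "class": clazz})
        genome_taxids[acc] = taxid

        # planted PII gene, island guaranteed to fit
        margin = flank + decoy_distance_min + nade_len + 100
        p_start = int(rng.integers(margin, L - margin - pii_len))
        p_end = p_start + pii_len - 1
        p_mid = (p_start + p_end) // 2
        pii_id = f"PII_{acc}"
        pii_rows.append(_hit("glnB_query", acc, contig, p_start, p_end, "+",
                             1e-40, pii_id))

        has_pair = rng.random() < p_pair
        if has_pair:
            dist = int(rng.integers(pair_distance_range[0],
                                    pair_distance_range[1] + 1))
            side = 1 if rng.random() < 0.5 else -1
            n_mid = p_mid + side * dist
            n_start = n_mid - nade_len // 2
            n_end = n_start + nade_len - 1
            nade_id = f"NadE_{acc}"
            nade_rows.append(_hit("nadE_query", acc, contig, n_start, n_end,
                                  "-" if side < 0 else "+", 1e-60, nade_id))
            real_dist = abs((n_start + n_end) // 2 - p_mid)
            expected.append({"genome": acc, "nade_protein_id": nade_id,
                             "midpoint_distance": int(real_dist),
                             "class": clazz, "phylum": phylum})

        if include_decoys:
            # nadE too far (inside island, >= decoy_distance_min away)
            d = int(rng.integers(decoy_distance_min, flank - nade_len // 2 - 10))
            far_mid = p_mid - d
            nade_rows.append(_hit("nadE_query", acc, contig,
                                  far_mid - nade_len // 2,
                                  far_mid + nade_len // 2 - 1, "+", 1e-50,
                                  f"NadE_far_{acc}"))
            # nadE with a failing e-value right next to the PII gene
            nade_rows.append(_hit("nadE_query", acc, contig, p_end + 50,
                                  p_end + 49 + nade_len, "+", 1e-4,
                                  f"NadE_weak_{acc}"))
            # PII hit whose window would run off the contig start
            edge_start = int(rng.integers(100, max(flank - pii_len - 100, 200)))
            pii_rows.append(_hit("glnB_query", acc, contig, edge_start,
                                 edge_start + pii_len - 1, "+", 1e-30,
                                 f"PII_edge_{acc}"))
            # weak PII hit (no island)
            pii_rows.append(_hit("glnB_query", acc, contig, p_start + 30_000,
                                 p_start + 30_000 + pii_len - 1, "+", 1e-3,
                                 f"PII_weak_{acc}"))
            # short contig: PII centred but no room for 10-kb flanks
            short = f"{acc}_c2"
            contigs.append({"genome": acc, "contig_id": short,
                            "length": 15_000})
            pii_rows.append(_hit("glnB_query", acc, short, 7_000,
                                 7_000 + pii_len - 1, "+", 1e-35,
                                 f"PII_short_{acc}"))

        if rng.random() < duplicate_species_fraction:
            # redundant assembly of the same species; must lose the dedupe
            dup = f"GCF_9{g:05d}.1"
            dup_contig = f"{dup}_c1"
            metas.append({"assembly_accession": dup, "taxid": taxid,
                          "species_taxid": species,
                          "assembly_level": "scaffold", "refseq_category": "na",
                          "organism_name": f"Synthetica bacterium sp{g} alt"})
            contigs.append({"genome": dup, "contig_id": dup_contig, "length": L})
            genome_taxids[dup] = taxid
            pii_rows.append(_hit("glnB_query", dup, dup_contig, p_start,
                                 p_end, "+", 1e-40, f"PII_{dup}"))
            nade_rows.append(_hit("nadE_query", dup, dup_contig, p_end + 100,
                                  p_end + 99 + nade_len, "+", 1e-60,
                                  f"NadE_{dup}"))

    class_counts = pd.Series([e["class"] for e in expected]).value_counts().to_dict() \
        if expected else {}
    truth = SyntheticTruth("genome_set", seed, {
        "n_genomes": n_genomes, "p_pair": p_pair,
        "pair_distance_range": list(pair_distance_range),
        "decoy_distance_min": decoy_distance_min,
        "expected_pairs": expected, "class_counts": class_counts,
    })
    return GenomeSet(
        metas=pd.DataFrame(metas),
        contigs=pd.DataFrame(contigs),
        pii_hits=pd.DataFrame(pii_rows),
        nade_hits=pd.DataFrame(nade_rows),
        lineages=pd.DataFrame(lineage_rows),
        genome_taxids=genome_taxids,
        truth=truth,
    )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def gen_protein_families(k: int = 3, n_per_family: int = 8,
                         ancestor_length: int = 200,
                         within_mutation_rate: float = 0.2,
                         between_divergence: float = 0.7,
                         seed: int | None = 0,
                         ) -> tuple[dict[str, str], SyntheticTruth]:
    """Protein families as point-mutated descendants of divergent ancestors.

    A random root sequence is mutated at ``between_divergence`` per site to
    give each family ancestor, and each ancestor at ``within_mutation_rate``
    to give its members, so within-family identity far exceeds between-family
    identity.  Returns ``{seq_id: sequence}`` plus true family labels.
    """
    if not 0 <= within_mutation_rate < 1 or not 0 < between_divergence < 1:
        raise ValueError("rates must lie in (0, 1)")
    if within_mutation_rate >= between_divergence:
        raise ValueError("within-family divergence must be below between-family")
    rng = substream(seed, "protein_families")
    root = rng.choice(AMINO_ACIDS, ancestor_length)
    seqs, labels = {}, {}
    for fam in range(k):
        ancestor = _mutate(root, between_divergence, rng)
        for m in range(n_per_family):
            sid = f"fam{fam}_seq{m}"
            seqs[sid] = "".join(_mutate(ancestor, within_mutation_rate, rng))
            labels[sid] = fam
    truth = SyntheticTruth("protein_families", seed, {
        "k": k, "n_per_family": n_per_family, "labels": labels,
        "within_mutation_rate": within_mutation_rate,
        "between_divergence": between_divergence,
    })
    return seqs, truth


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs.items():
            fh.write(f">{sid}\n{s}\n")


def gen_lfq_table(n_proteins: int = 200, n_enriched: int = 5,
                  enrichment_factor: float = 50.0, seed: int | None = 0,
                  ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Label-free intensity table with planted bait-enriched proteins."""
    rng = substream(seed, "lfq_table")
    base = rng.lognormal(mean=20.0, sigma=1.0, size=(n_proteins, 2))
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    enriched = sorted(rng.choice(n_proteins, n_enriched, replace=False).tolist())
    df = pd.DataFrame({
        "protein_id": ids,
        "bait_f1": base[:, 0] * (1 + 0.1 * rng.standard_normal(n_proteins)),
        "bait_f2": base[:, 1] * (1 + 0.1 * rng.standard_normal(n_proteins)),
        "control_f1": base[:, 0] * (1 + 0.1 * rng.standard_normal(n_proteins)),
        "control_f2": base[:, 1] * (1 + 0.1 * rng.standard_normal(n_proteins)),
    })
    for i in enriched:
        df.loc[i, ["bait_f1", "bait_f2"]] *= enrichment_factor
    df[["bait_f1", "bait_f2", "control_f1", "control_f2"]] = \
        df[["bait_f1", "bait_f2", "control_f1", "control_f2"]].clip(lower=0.0)
    truth = SyntheticTruth("lfq_table", seed, {
        "enriched_ids": [ids[i] for i in enriched],
        "enrichment_factor": enrichment_factor,
    })
    return df, truth
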