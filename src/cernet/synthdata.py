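"""Synthetic two-group cohort generator with planted structure.

Emulates a case/control skin-biopsy cohort (psoriasis vs healthy) at desk
scale: negative-binomial counts for mRNAs and lncRNAs, NB counts (later
TPM-scaled) for miRNAs, planted differential expression, block-structured
co-expression, and planted ceRNA circuits in which a miRNA represses both
a lncRNA and an mRNA whose residual levels are additionally coupled
through a shared "sponge" latent factor.  Transcript sequences literally
contain the reverse-complement binding sites of their circuit miRNAs, and
an interaction whitelist lists all planted miRNA-target pairs plus decoys.

Everything is driven by one seed: a fixed config reproduces byte-identical
matrices, sequences and files.

Latent model (log2 scale), per feature f and sample j with group
indicator g_j in {0, 1}:

    lambda_fj = b_f + delta_f * g_j [+ u_{block(f), j}]        (background)
    lambda_mir,j  += e_j                                       (circuit miRNA)
    lambda_lnc,j  += -rho * e_j + s * z_j                      (circuit lncRNA)
    lambda_mrna,j += -rho * e_j + s * z_j                      (circuit mRNA)

with e, z ~ N(0, latent_sd^2) per circuit, rho the repression coefficient
and s = sponge_strength.  Counts are NB with mean 2^lambda and variance
mu + dispersion * mu^2 (gamma-Poisson).  In expectation this yields
corr(lnc, mRNA) > 0 and corr(miR, lnc), corr(miR, mRNA) < 0.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, SyntheticTruth
from . import io as cio

_DNA_COMP = str.maketrans("ACGTU", "TGCAA")
_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Counts of features/samples must be positive; fractions live in [0, 1];
    ``n_circuits`` may not exceed the smallest feature-class size.
    """

    n_mrna: int = 300
    n_lncrna: int = 80
    n_mirna: int = 60
    n_per_group: int = 50
    de_fraction: float = 0.1
    lfc_mean: float = 3.0          # mean |log2FC| of planted DE
    lfc_sd: float = 0.25
    dispersion: float = 0.1        # NB: var = mu + dispersion * mu^2
    n_circuits: int = 10
    sponge_strength: float = 0.8   # lncRNA-mRNA coupling weight in [0, 1]
    seed: int = 0
    utr_len: int = 400
    lnc_len: int = 600
    # -- secondary knobs ----------------------------------------------------
    repression: float = 0.7        # miRNA -> target latent repression
    latent_sd: float = 0.8         # sd (log2) of circuit latent factors
    n_blocks: int = 4              # co-expression blocks among background RNAs
    block_sd: float = 0.5          # sd (log2) of the per-block sample factor
    decoy_fraction: float = 0.5    # decoys as a fraction of planted pairs
    n_decoys: int | None = None    # absolute decoy count (overrides fraction)
    site_mode: str = "full"        # "full" or "seed" planted site span
    mirna_len: int = 22
    # ultra-abundant constitutive miRNAs (never DE, never in circuits) that
    # dominate the library, as in real miRNomes; they stabilize the TPM
    # denominator so planted miRNA fold changes survive per-sample scaling
    n_stable_mirna: int = 8
    stable_log2_min: float = 10.0
    stable_log2_max: float = 12.0
    base_log2_min: float = 3.0
    base_log2_max: float = 9.0
    n_gene_sets: int = 5
    gene_set_size: int = 30

    def __post_init__(self):
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_per_group",
                     "utr_len", "lnc_len", "mirna_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("de_fraction", "sponge_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.decoy_fraction < 0:
            raise ValueError("decoy_fraction must be >= 0")
        if self.n_circuits < 0:
            raise ValueError("n_circuits must be >= 0")
        if self.n_stable_mirna < 0 or self.n_stable_mirna >= self.n_mirna:
            raise ValueError("n_stable_mirna must be in [0, n_mirna)")
        if self.n_circuits > min(self.n_lncrna, self.n_mrna,
                                 self.n_mirna - self.n_stable_mirna):
            raise ValueError(
                f"n_circuits={self.n_circuits} exceeds the smallest feature "
                f"class (min of n_lncrna={self.n_lncrna}, "
                f"n_mrna={self.n_mrna}, n_mirna={self.n_mirna} minus "
                f"n_stable_mirna={self.n_stable_mirna})")
        if self.site_mode not in ("full", "seed"):
            raise ValueError("site_mode must be 'full' or 'seed'")
        if not 18 <= self.mirna_len <= 26:
            raise ValueError("mirna_len must be in 18..26")


@dataclass
class Cohort:
    """In-memory bundle produced by :func:`generate_cohort`."""

    config: CohortConfig
    rna: ExpressionMatrix          # mRNA + lncRNA counts
    mirna: ExpressionMatrix        # miRNA counts (convert with counts_to_tpm)
    sequences: dict                # {"lncrna": {...}, "utr3": {...}, "mirna": {...}}
    whitelist: pd.DataFrame        # columns mirna_id, target_id, source
    gene_sets: list = field(default_factory=list)
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)
    blocks: pd.Series | None = None  # co-expression block per RNA feature (-1 = none)


def reverse_complement(seq: str, alphabet: str = "DNA") -> str:
    rc = seq.upper().translate(_DNA_COMP)[::-1]
    if alphabet == "RNA":
        rc = rc.replace("T", "U")
    return rc


def embed_site(sequence: str, mirna: str, start: int, span: int | None = None,
               name: str = "transcript") -> str:
    """Write the reverse complement of the miRNA's first ``span`` positions
    (default: full length) into ``sequence`` at 0-based offset ``start``.

    The site alphabet follows the host sequence (DNA target for a DNA
    transcript).  Length is unchanged; overrunning the end raises, naming
    the transcript.
    """
    span = len(mirna) if span is None else span
    site = reverse_complement(mirna[:span], alphabet="DNA")
    if "U" in sequence.upper():
        site = site.replace("T", "U")
    if start < 0 or start + len(site) > len(sequence):
        raise ValueError(
            f"site [{start}, {start + len(site)}) overruns {name} "
            f"(length {len(sequence)})")
    return sequence[:start] + site + sequence[start + len(site):]


def counts_to_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample scaling of small-RNA counts to tags-per-million."""
    total = counts.sum(axis=0).replace(0, 1)
    return counts / total * 1e6


def _nb_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def _random_seq(rng, length: int, letters: np.ndarray) -> str:
    return "".join(rng.choice(letters, size=length))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort for a configuration.

    Returns matrices, sequences, whitelist, gene sets and the planted
    ground truth; a fixed config yields byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    mrna_ids = [f"PCG{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    lnc_ids = [f"LNC{i:04d}" for i in range(1, cfg.n_lncrna + 1)]
    mir_ids = [f"MIR{i:04d}" for i in range(1, cfg.n_mirna + 1)]
    samples = ([f"H{i:03d}" for i in range(1, cfg.n_per_group + 1)]
               + [f"P{i:03d}" for i in range(1, cfg.n_per_group + 1)])
    groups = pd.Series(["healthy"] * cfg.n_per_group
                       + ["psoriasis"] * cfg.n_per_group,
                       index=samples, name="group")
    g = np.array([0] * cfg.n_per_group + [1] * cfg.n_per_group, dtype=float)

    def _class_setup(ids, eligible=None):
        n = len(ids)
        base = rng.uniform(cfg.base_log2_min, cfg.base_log2_max, n)
        delta = np.zeros(n)
        pool = np.arange(n) if eligible is None else np.asarray(eligible)
        k = int(round(cfg.de_fraction * pool.size))
        de_idx = rng.choice(pool, size=k, replace=False) if k else np.array([], int)
        signs = rng.choice([-1.0, 1.0], size=k)
        mags = np.clip(rng.normal(cfg.lfc_mean, cfg.lfc_sd, k), 0.5, None)
        delta[de_idx] = signs * mags
        return base, delta

    # the last n_stable_mirna miRNAs form the constitutive high-abundance
    # tier: never DE, never circuit members
    n_var_mir = cfg.n_mirna - cfg.n_stable_mirna
    base_m, delta_m = _class_setup(mrna_ids)
    base_l, delta_l = _class_setup(lnc_ids)
    base_r, delta_r = _class_setup(mir_ids, eligible=np.arange(n_var_mir))
    if cfg.n_stable_mirna:
        base_r[n_var_mir:] = rng.uniform(cfg.stable_log2_min,
                                         cfg.stable_log2_max,
                                         cfg.n_stable_mirna)
        delta_r[n_var_mir:] = 0.0

    # planted circuits: disjoint per role, members forced DE with coherent signs
    c_lnc = rng.choice(cfg.n_lncrna, cfg.n_circuits, replace=False)
    c_mrna = rng.choice(cfg.n_mrna, cfg.n_circuits, replace=False)
    c_mir = rng.choice(n_var_mir, cfg.n_circuits, replace=False)
    c_dir = rng.choice([-1.0, 1.0], cfg.n_circuits)
    c_mag = np.clip(rng.normal(cfg.lfc_mean, cfg.lfc_sd, (cfg.n_circuits, 3)),
                    0.5, None)
    for k in range(cfg.n_circuits):
        delta_l[c_lnc[k]] = c_dir[k] * c_mag[k, 0]
        delta_m[c_mrna[k]] = c_dir[k] * c_mag[k, 1]
        delta_r[c_mir[k]] = -c_dir[k] * c_mag[k, 2]
    circuits = [(lnc_ids[c_lnc[k]], mir_ids[c_mir[k]], mrna_ids[c_mrna[k]])
                for k in range(cfg.n_circuits)]

    # co-expression blocks among background (non-circuit) mRNAs/lncRNAs
    n_s = len(samples)
    block_m = rng.integers(0, cfg.n_blocks, cfg.n_mrna)
    block_l = rng.integers(0, cfg.n_blocks, cfg.n_lncrna)
    block_m[c_mrna] = -1
    block_l[c_lnc] = -1
    u = rng.normal(0.0, cfg.block_sd, (cfg.n_blocks, n_s)) if cfg.block_sd > 0 \
        else np.zeros((cfg.n_blocks, n_s))

    lam_m = base_m[:, None] + delta_m[:, None] * g[None, :]
    lam_l = base_l[:, None] + delta_l[:, None] * g[None, :]
    lam_r = base_r[:, None] + delta_r[:, None] * g[None, :]
    for arr, blocks in ((lam_m, block_m), (lam_l, block_l)):
        inblk = blocks >= 0
        arr[inblk] += u[blocks[inblk]]

    # circuit latents: repression (e) and sponge coupling (z)
    e = rng.normal(0.0, cfg.latent_sd, (cfg.n_circuits, n_s))
    z = rng.normal(0.0, cfg.latent_sd, (cfg.n_circuits, n_s))
    s = cfg.sponge_strength
    for k in range(cfg.n_circuits):
        lam_r[c_mir[k]] += e[k]
        coupled = -cfg.repression * e[k] + s * z[k]
        lam_l[c_lnc[k]] += coupled
        lam_m[c_mrna[k]] += coupled

    counts_m = _nb_counts(rng, 2.0 ** lam_m, cfg.dispersion)
    counts_l = _nb_counts(rng, 2.0 ** lam_l, cfg.dispersion)
    counts_r = _nb_counts(rng, 2.0 ** lam_r, cfg.dispersion)

    rna_values = pd.DataFrame(np.vstack([counts_m, counts_l]),
                              index=mrna_ids + lnc_ids, columns=samples)
    biotype = pd.Series(["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lncrna
                        + ["miRNA"] * cfg.n_mirna,
                        index=mrna_ids + lnc_ids + mir_ids, name="biotype")
    rna = ExpressionMatrix(rna_values, biotype, groups)
    mirna = ExpressionMatrix(
        pd.DataFrame(counts_r, index=mir_ids, columns=samples), biotype, groups)

    # sequences, with planted reverse-complement sites for circuit miRNAs
    mir_seqs = {mid: _random_seq(rng, cfg.mirna_len, _RNA) for mid in mir_ids}
    lnc_seqs = {lid: _random_seq(rng, cfg.lnc_len, _DNA) for lid in lnc_ids}
    utr_seqs = {mid: _random_seq(rng, cfg.utr_len, _DNA) for mid in mrna_ids}
    span = cfg.mirna_len if cfg.site_mode == "full" else 8
    planted_sites = []
    for lnc, mir, mrna in circuits:
        for seqs, tid, maxlen in ((lnc_seqs, lnc, cfg.lnc_len),
                                  (utr_seqs, mrna, cfg.utr_len)):
            start = int(rng.integers(0, maxlen - span + 1))
            seqs[tid] = embed_site(seqs[tid], mir_seqs[mir], start,
                                   span=span, name=tid)
            planted_sites.append((mir, tid, start + 1, start + span))

    # whitelist: planted pairs + decoys (same source label for all rows)
    planted_pairs = sorted({(mir, lnc) for lnc, mir, _ in circuits}
                           | {(mir, mrna) for _, mir, mrna in circuits})
    n_decoys = (cfg.n_decoys if cfg.n_decoys is not None
                else int(round(cfg.decoy_fraction * len(planted_pairs))))
    all_targets = lnc_ids + mrna_ids
    decoys, seen = [], set(planted_pairs)
    attempts = 0
    while len(decoys) < n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        pair = (mir_ids[rng.integers(0, cfg.n_mirna)],
                all_targets[rng.integers(0, len(all_targets))])
        if pair not in seen:
            seen.add(pair)
            decoys.append(pair)
    wl_rows = [{"mirna_id": m, "target_id": t, "source": "synthdb"}
               for m, t in planted_pairs + sorted(decoys)]
    whitelist = pd.DataFrame(wl_rows, columns=["mirna_id", "target_id", "source"])

    # gene sets: one enriched in circuit mRNAs, the rest random background
    gene_sets = []
    circuit_mrnas = sorted(c[2] for c in circuits)
    if cfg.n_gene_sets > 0 and cfg.n_mrna >= 2:
        size = min(cfg.gene_set_size, cfg.n_mrna)
        fill = [m for m in mrna_ids if m not in circuit_mrnas]
        extra = list(rng.choice(fill, size=max(0, size - len(circuit_mrnas)),
                                replace=False)) if fill else []
        gene_sets.append(GeneSet("CIRCUIT_PATHWAY",
                                 "planted ceRNA circuit mRNAs plus background",
                                 frozenset(circuit_mrnas + extra)))
        for i in range(1, cfg.n_gene_sets):
            members = rng.choice(mrna_ids, size=size, replace=False)
            gene_sets.append(GeneSet(f"RANDOM_SET_{i}",
                                     "random background mRNAs",
                                     frozenset(members)))

    de_features = set()
    for ids, delta in ((mrna_ids, delta_m), (lnc_ids, delta_l),
                       (mir_ids, delta_r)):
        for fid, d in zip(ids, delta):
            if d != 0:
                de_features.add((fid, 1 if d > 0 else -1))

    truth = SyntheticTruth(de_features=de_features, circuits=circuits,
                           planted_sites=planted_sites)
    sequences = {"lncrna": lnc_seqs, "utr3": utr_seqs, "mirna": mir_seqs}
    blocks = pd.Series(np.concatenate([block_m, block_l]),
                       index=mrna_ids + lnc_ids, name="block")
    return Cohort(cfg, rna, mirna, sequences, whitelist, gene_sets, truth,
                  blocks)


# ---------------------------------------------------------------------------
# fixture IO

FIXTURE_FILES = {
    "rna_counts": "counts_rna.tsv",
    "mirna_counts": "counts_mirna.tsv",
    "biotypes": "biotypes.tsv",
    "groups": "groups.tsv",
    "lncrna_fasta": "lncrna.fa",
    "utr3_fasta": "utr3.fa",
    "mirna_fasta": "mirna.fa",
    "whitelist": "whitelist.tsv",
    "gmt": "gene_sets.gmt",
    "truth": "truth.json",
    "config": "cohort_config.json",
}


def write_fixture(cohort: Cohort, directory) -> dict:
    """Write the cohort to a directory of plain-text files.

    Returns a name -> path mapping (see ``FIXTURE_FILES``).  Re-reading
    with :func:`read_fixture` reproduces the in-memory objects exactly.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / v for k, v in FIXTURE_FILES.items()}
    cio.write_expression_tsv(cohort.rna.values, paths["rna_counts"])
    cio.write_expression_tsv(cohort.mirna.values, paths["mirna_counts"])
    cohort.rna.biotype.rename_axis("feature_id").to_csv(paths["biotypes"], sep="\t")
    cohort.rna.groups.rename_axis("sample_id").to_csv(paths["groups"], sep="\t")
    cio.write_fasta(cohort.sequences["lncrna"], paths["lncrna_fasta"])
    cio.write_fasta(cohort.sequences["utr3"], paths["utr3_fasta"])
    cio.write_fasta(cohort.sequences["mirna"], paths["mirna_fasta"])
    cohort.whitelist.to_csv(paths["whitelist"], sep="\t", index=False)
    cio.write_gmt(cohort.gene_sets, paths["gmt"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "de_features": sorted([f, int(d)] for f, d in
                                  cohort.truth.de_features),
            "circuits": [list(c) for c in cohort.truth.circuits],
            "planted_sites": [list(s) for s in cohort.truth.planted_sites],
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1,
                  sort_keys=True)
        fh.write("\n")
    return paths


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        data = json.load(fh)
    return SyntheticTruth(
        de_features={(f, int(d)) for f, d in data["de_features"]},
        circuits=[tuple(c) for c in data["circuits"]],
        planted_sites=[tuple(s) for s in data["planted_sites"]],
    )


def read_fixture(directory) -> Cohort:
    """Inverse of :func:`write_fixture` (round-trip exact)."""
    d = Path(directory)
    p = {k: d / v for k, v in FIXTURE_FILES.items()}
    with open(p["config"]) as fh:
        cfg = CohortConfig(**json.load(fh))
    biotype = pd.read_csv(p["biotypes"], sep="\t",
                          index_col=0)["biotype"].rename_axis(None)
    groups = pd.read_csv(p["groups"], sep="\t",
                         index_col=0)["group"].rename_axis(None)
    rna = ExpressionMatrix(cio.read_expression_tsv(p["rna_counts"]),
                           biotype, groups)
    mirna = ExpressionMatrix(cio.read_expression_tsv(p["mirna_counts"]),
                             biotype, groups)
    sequences = {
        "lncrna": cio.read_fasta(p["lncrna_fasta"]),
        "utr3": cio.read_fasta(p["utr3_fasta"]),
        "mirna": cio.read_fasta(p["mirna_fasta"]),
    }
    whitelist = cio.read_whitelist(p["whitelist"])
    gene_sets = cio.read_gmt(p["gmt"])
    return Cohort(cfg, rna, mirna, sequences, whitelist, gene_sets,
                  read_truth(p["truth"]))
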