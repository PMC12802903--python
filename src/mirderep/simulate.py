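"""Synthetic pituitary-style RNA-seq / small-RNA-seq data with planted ground truth.

The generator emulates the input landscape of a miRNA-target derepression
study: two count matrices (exon- and intron-mapping reads) over a control
genotype and one or two mutant genotypes, a small-RNA library with adapters,
randomized flanks and spike-ins, a 3'-UTR length table in which miRNA targets
are length-biased, and a target-prediction table.  Two effect classes are
planted:

* transcriptional repression on a "TF target" gene set — the fold change is
  written into exon *and* intron counts, because a transcriptional change
  moves the pre-mRNA along with the mature mRNA;
* post-transcriptional derepression on "miRNA target" gene sets — the fold
  change is written into exon counts only, leaving intron counts flat.

All randomness flows through named streams derived from the master seed, so
adding one output object never perturbs another, and every artifact is byte
reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diffexpr import CountMatrix

__all__ = [
    "MirnaFamily",
    "SimulationConfig",
    "PlantedTruth",
    "default_mirna_families",
    "simulate_counts",
    "simulate_small_rna_reads",
    "simulate_utr_table",
    "simulate_predictions",
    "mirna_dictionary_frame",
    "write_fastq",
]

# Named sub-streams of the master seed (one per output object).
_STREAMS = {
    "structure": 0,   # baselines, set membership, library sizes
    "exon": 1,
    "intron": 2,
    "reads": 3,
    "utr": 4,
    "predictions": 5,
    "library": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class MirnaFamily:
    """A mature-miRNA family: shared seed, hence shared target repertoire."""

    name: str
    members: tuple[tuple[str, str], ...]  # (mirna_id, mature sequence, RNA alphabet)
    abundance: float                      # baseline relative abundance (control)
    group_fold: Mapping[str, float] = field(default_factory=dict)  # group -> fold vs control

    def fold(self, group: str) -> float:
        return float(self.group_fold.get(group, 1.0))


def default_mirna_families() -> tuple[MirnaFamily, ...]:
    """Default family panel.

    The two miR-200 families carry the planted abundance collapse (about 5-fold
    in the heterozygous-like group and 10-fold in the homozygous-like group,
    the scale of the measured decreases in the system this emulates); the
    remaining abundant families are stable fillers.
    """
    return (
        MirnaFamily(
            "miR-200b/c/429",
            (
                ("miR-200b-3p", "UAAUACUGCCUGGUAAUGAUGA"),
                ("miR-200c-3p", "UAAUACUGCCGGGUAAUGAUGGA"),
                ("miR-429-3p", "UAAUACUGUCUGGUAAUGCCGU"),
            ),
            abundance=0.20,
            group_fold={"het": 0.2, "hom": 0.1},
        ),
        MirnaFamily(
            "miR-200a/141",
            (
                ("miR-200a-3p", "UAACACUGUCUGGUAACGAUGU"),
                ("miR-141-3p", "UAACACUGUCUGGUAAAGAUGG"),
            ),
            abundance=0.10,
            group_fold={"het": 0.2, "hom": 0.1},
        ),
        MirnaFamily("miR-7", (("miR-7a-5p", "UGGAAGACUAGUGAUUUUGUUGU"),), abundance=0.30),
        MirnaFamily("let-7", (("let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU"),), abundance=0.25),
        MirnaFamily("miR-26", (("miR-26a-5p", "UUCAAGUAAUCCAGGAUAGGCU"),), abundance=0.15),
    )


# Synthetic spike-in species (exogenous accounting controls; invented
# sequences, deliberately not real Xenopus/C. elegans spike-in sequences).
SPIKE_INS: tuple[tuple[str, str], ...] = (
    ("spikein-1", "ACGTGTCATGCGATACGTTCAG"),
    ("spikein-2", "TGCACGATTCAGGTACGCTAAC"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs, with study-scale defaults.

    ``nb_dispersion`` parameterizes a mean-dependent dispersion trend
    ``alpha(mu) = a0 + a1/mu`` (asymptotic dispersion and trend coefficient);
    the default (0.02, 1.5) is the scale seen for isogenic-mouse bulk tissue
    replicates.  ``tf_log2fc`` applies to exon and intron counts of TF-target
    genes; ``mir_log2fc`` applies to exon counts only of miRNA-target genes
    (default log2(1.25), the modest derepression typical of losing one miRNA
    family).  ``utr_length_bias`` multiplicatively inflates target UTR
    lengths, creating the confound that motivates length matching.
    ``utr_lfc_per_log2`` plants a UTR-length-dependent (target-independent)
    exon fold change, used to demonstrate that matching removes the length
    confound.  ``group_effect_scale`` scales planted effects per group
    (control fixed at 0).
    """

    n_genes: int = 2000
    n_samples_per_group: int = 4
    groups: tuple[str, ...] = ("control", "het", "hom")
    nb_dispersion: tuple[float, float] = (0.02, 1.5)
    library_size_range: tuple[float, float] = (0.8e6, 1.3e6)
    tf_target_fraction: float = 0.10
    tf_log2fc: float = -1.0
    mir_target_fraction: float = 0.15
    mir_log2fc: float = float(np.log2(1.25))
    utr_length_bias: float = 0.5
    utr_lfc_per_log2: float = 0.0
    intron_fraction: float = 0.20
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    mirna_families: tuple[MirnaFamily, ...] = field(default_factory=default_mirna_families)
    group_effect_scale: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "het": 1.0, "hom": 1.0}
    )
    spikein_fraction: float = 0.01
    frac_lowq_reads: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        for frac, name in (
            (self.tf_target_fraction, "tf_target_fraction"),
            (self.mir_target_fraction, "mir_target_fraction"),
            (self.spikein_fraction, "spikein_fraction"),
            (self.frac_lowq_reads, "frac_lowq_reads"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tf_target_fraction + self.mir_target_fraction > 1.0:
            raise ValueError("planted set fractions must sum to at most 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if self.utr_length_bias < 0:
            raise ValueError("utr_length_bias must be >= 0")
        a0, a1 = self.nb_dispersion
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion trend parameters must be >= 0")
        for fam in self.mirna_families:
            if fam.abundance <= 0:
                raise ValueError(f"family {fam.name} abundance must be > 0")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        """Load a config from a nested key/value YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mirna_families" in raw:
            raw["mirna_families"] = tuple(
                MirnaFamily(
                    name=f["name"],
                    members=tuple((m["id"], m["sequence"]) for m in f["members"]),
                    abundance=f["abundance"],
                    group_fold=f.get("group_fold", {}),
                )
                for f in raw["mirna_families"]
            )
        for key in ("groups", "nb_dispersion", "library_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class PlantedTruth:
    """Ground truth the generator committed to.

    ``genes`` is indexed by gene_id with columns ``set_label`` (``tf_target``,
    ``mir_target_of:<family>`` or ``none``), ``utr_length``, ``baseline``, and
    per-group true log2 fold changes ``exon_lfc_<group>`` /
    ``intron_lfc_<group>``.  ``mirnas`` is indexed by mirna_id with ``family``
    and per-group true relative abundances.  Invariants: miRNA targets have
    zero true intron fold change; TF targets have equal exon and intron fold
    changes.
    """

    genes: pd.DataFrame
    mirnas: pd.DataFrame

    def gene_set(self, label: str) -> pd.Index:
        return self.genes.index[self.genes["set_label"] == label]

    @property
    def tf_targets(self) -> pd.Index:
        return self.gene_set("tf_target")

    def mir_targets(self, family: str | None = None) -> pd.Index:
        lab = self.genes["set_label"]
        if family is None:
            return self.genes.index[lab.str.startswith("mir_target_of:")]
        return self.genes.index[lab == f"mir_target_of:{family}"]


def _assign_structure(config: SimulationConfig) -> pd.DataFrame:
    """Gene baselines, set membership and UTR lengths (the 'structure' and
    'utr' streams)."""
    rng = _rng(config.seed, "structure")
    n = config.n_genes
    genes = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    labels = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    n_tf = int(round(config.tf_target_fraction * n))
    n_mir = int(round(config.mir_target_fraction * n))
    labels[order[:n_tf]] = "tf_target"
    mir_idx = order[n_tf : n_tf + n_mir]
    fams = [f.name for f in config.mirna_families] or ["mirX"]
    for j, gi in enumerate(mir_idx):
        labels[gi] = f"mir_target_of:{fams[j % len(fams)]}"

    rng_utr = _rng(config.seed, "utr")
    log2_len = rng_utr.normal(10.2, 1.2, n)  # median ~1.2 kb, realistic 3'-UTR scale
    length = 2.0 ** log2_len
    is_mir = np.char.startswith(labels.astype(str), "mir_target_of:")
    length[is_mir] *= 1.0 + config.utr_length_bias
    length = np.maximum(np.rint(length), 30).astype(int)

    return pd.DataFrame({"set_label": labels, "baseline": baseline, "utr_length": length}, index=genes)


def _true_lfc(config: SimulationConfig, structure: pd.DataFrame) -> tuple[dict, dict]:
    """Per-group true exon and intron log2FC arrays."""
    labels = structure["set_label"].to_numpy(dtype=object)
    is_tf = labels == "tf_target"
    is_mir = np.char.startswith(labels.astype(str), "mir_target_of:")
    log2_len = np.log2(structure["utr_length"].to_numpy(float))
    len_dev = log2_len - log2_len.mean()

    exon_lfc, intron_lfc = {}, {}
    for g in config.groups:
        s = float(config.group_effect_scale.get(g, 1.0 if g != config.groups[0] else 0.0))
        e = np.zeros(len(structure))
        e[is_tf] += config.tf_log2fc * s
        e[is_mir] += config.mir_log2fc * s
        e += config.utr_lfc_per_log2 * s * len_dev
        i = np.zeros(len(structure))
        i[is_tf] += config.tf_log2fc * s  # transcriptional: pre-mRNA moves too
        exon_lfc[g], intron_lfc[g] = e, i
    return exon_lfc, intron_lfc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with Var = mu + alpha mu^2; alpha -> 0 degenerates to Poisson."""
    out = np.empty_like(mu, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, CountMatrix, PlantedTruth]:
    """Draw exon and intron count matrices with planted effects.

    Counts are NB with mean ``baseline x library factor x 2^(true log2FC)``
    and dispersion from the configured trend.  The intron matrix shares gene
    ids and library factors with the exon matrix (same library, sparser
    intronic signal at ``intron_fraction`` of the exon baseline).
    """
    structure = _assign_structure(config)
    exon_lfc, intron_lfc = _true_lfc(config, structure)

    rng_s = _rng(config.seed, "library")
    groups = [g for g in config.groups for _ in range(config.n_samples_per_group)]
    samples = [f"{g}_{i+1}" for g in config.groups for i in range(config.n_samples_per_group)]
    lo, hi = config.library_size_range
    lib = rng_s.uniform(lo, hi, len(samples))
    lib_factor = lib / np.exp(np.mean(np.log(lib)))

    a0, a1 = config.nb_dispersion
    baseline = structure["baseline"].to_numpy()
    counts = {}
    for kind, base, lfc, stream in (
        ("exon", baseline, exon_lfc, "exon"),
        ("intron", baseline * config.intron_fraction, intron_lfc, "intron"),
    ):
        rng = _rng(config.seed, stream)
        alpha = a0 + a1 / base
        mat = np.empty((config.n_genes, len(samples)), dtype=np.int64)
        for s, (samp, grp) in enumerate(zip(samples, groups)):
            mu = base * lib_factor[s] * 2.0 ** lfc[grp]
            mat[:, s] = _nb_draw(rng, mu, alpha)
        counts[kind] = pd.DataFrame(mat, index=structure.index, columns=samples)

    meta = pd.DataFrame({"group": groups, "cohort": "sim"}, index=pd.Index(samples, name="sample_id"))
    genes = structure.copy()
    for g in config.groups:
        genes[f"exon_lfc_{g}"] = exon_lfc[g]
        genes[f"intron_lfc_{g}"] = intron_lfc[g]

    mir_rows = []
    for fam in config.mirna_families:
        for mid, _seq in fam.members:
            row = {"family": fam.name}
            for g in config.groups:
                row[f"abundance_{g}"] = fam.abundance / len(fam.members) * (
                    1.0 if g == config.groups[0] else fam.fold(g)
                )
            mir_rows.append(pd.Series(row, name=mid))
    mirnas = pd.DataFrame(mir_rows)
    mirnas.index.name = "mirna_id"

    truth = PlantedTruth(genes=genes, mirnas=mirnas)
    return (
        CountMatrix(counts["exon"], meta),
        CountMatrix(counts["intron"], meta),
        truth,
    )


def simulate_utr_table(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """3'-UTR length table (gene_id, utr_length) for the simulated genes.

    Lengths are assigned once, at gene-structure time (log-normal for
    nontargets, inflated by ``1 + utr_length_bias`` for miRNA targets), so
    that planted fold changes may depend on them; this accessor exports them
    in the two-column input format the analysis consumes.
    """
    del config
    return truth.genes[["utr_length"]].reset_index()


def simulate_predictions(config: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Target-prediction table for the planted miRNA target sets.

    One record per (gene, family): cumulative weighted context++-style score
    (negative; more negative = stronger predicted repression) and a
    conservation flag.  Scores are exponentially distributed and independent
    of the planted effect.
    """
    rng = _rng(config.seed, "predictions")
    rows = []
    for fam in config.mirna_families:
        targets = truth.mir_targets(fam.name)
        scores = -rng.exponential(0.25, len(targets)) - 0.01
        conserved = rng.random(len(targets)) < 0.4
        for g, s, c in zip(targets, scores, conserved):
            rows.append((g, fam.name, float(s), bool(c)))
    return pd.DataFrame(rows, columns=["gene_id", "family", "context_score", "conserved"])


def mirna_dictionary_frame(config: SimulationConfig) -> pd.DataFrame:
    """Mature-miRNA dictionary (TSV layout) including spike-in species."""
    rows = [
        (mid, fam.name, seq, False, False)
        for fam in config.mirna_families
        for mid, seq in fam.members
    ]
    rows += [(sid, "spike-in", seq, True, False) for sid, seq in SPIKE_INS]
    return pd.DataFrame(
        rows, columns=["mirna_id", "family", "sequence", "is_spike_in", "is_size_standard"]
    )


def simulate_small_rna_reads(
    config: SimulationConfig,
    adapter3: str,
    n_reads: int,
    group: str | None = None,
    adapter5: str = "",
) -> tuple[list[tuple[str, str, str]], pd.Series]:
    """Small-RNA reads with randomized flanks, 3' adapter and spike-ins.

    Each read is ``4 random nt + mature sequence + 4 random nt + adapter3``
    (U already converted to T, as a sequencer reports).  A configurable
    fraction of reads carries one sub-Q30 base to exercise the quality
    filter; all other bases are Q37.  Spike-ins enter at
    ``config.spikein_fraction`` each.  Returns 4-tuple-free FASTQ records as
    ``(read_id, sequence, quality)`` plus the true multinomial species counts.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    group = group or config.groups[0]
    rng = _rng(config.seed, "reads")

    species, weights = [], []
    for fam in config.mirna_families:
        for mid, seq in fam.members:
            species.append((mid, seq.replace("U", "T").upper()))
            weights.append(fam.abundance / len(fam.members) * (1.0 if group == config.groups[0] else fam.fold(group)))
    bio_total = sum(weights)
    spike_total = config.spikein_fraction * len(SPIKE_INS)
    weights = [w / bio_total * (1.0 - spike_total) for w in weights]
    for sid, seq in SPIKE_INS:
        species.append((sid, seq))
        weights.append(config.spikein_fraction)

    truth = pd.Series(0, index=[sid for sid, _ in species], dtype=int, name="true_count")
    records: list[tuple[str, str, str]] = []
    if n_reads == 0:
        return records, truth

    counts = rng.multinomial(n_reads, np.asarray(weights) / np.sum(weights))
    truth[:] = counts
    bases = np.array(list("ACGT"))
    adapter3 = adapter3.replace("U", "T").upper()
    r = 0
    for (sid, seq), c in zip(species, counts):
        for _ in range(c):
            flank5 = "".join(rng.choice(bases, 4))
            flank3 = "".join(rng.choice(bases, 4))
            full = flank5 + seq + flank3 + adapter3
            qual = ["F"] * len(full)  # Q37
            if rng.random() < config.frac_lowq_reads:
                qual[int(rng.integers(len(full)))] = "5"  # one Q20 base
            records.append((f"read{r:07d}:{sid}", full, "".join(qual)))
            r += 1
    # shuffle so species order carries no information
    perm = rng.permutation(len(records))
    records = [records[i] for i in perm]
    return records, truth


def write_fastq(records: Sequence[tuple[str, str, str]], path: str) -> None:
    """Write (id, seq, qual) records as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
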