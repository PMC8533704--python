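"""Synthetic somatic-variant cohorts with known ground truth.

The generator emulates the statistical structure a targeted-panel
mutational-signature analysis of ovarian clear cell carcinoma assumes:

* 55-sample cohorts whose 96-motif catalogs are mixtures of three
  ground-truth signatures, with mixture weights varying by the
  mutation-defined subgroup (ARID1A / PIK3CA / Double hit / Undetermined);
* recurrent driver events — an in-frame 3-bp deletion hotspot in the
  first driver gene and a missense hotspot in the second — injected per
  subgroup at configurable hotspot fractions;
* a configurable fraction of samples with APOBEC-style tCw enrichment;
* planted kataegis clusters with known location and spacing;
* read-depth / strand-count / quality noise targeted at designated
  variants so every rule of the filter cascade has positive and negative
  ground-truth examples;
* five-locus MSI profiles, with MSI-high samples hypermutated so that
  MSI-H and high mutational load tend to co-occur.

Mutations are placed on a toy genome of three 10-Mb chromosomes; the
41-base contexts are synthesized per variant, consistent with the drawn
motif, with flanks beyond the trinucleotide drawn uniformly.  Everything
is deterministic for a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .motifs import BASES, MOTIF_ORDER, SUBSTITUTIONS, parse_motif, revcomp
from .records import CONTEXT_FLANK, VariantRecord
from .variant_filter import strand_bias_phred as _strand_bias_phred

SUBGROUPS = ("ARID1A", "PIK3CA", "Double hit", "Undetermined")
MSI_LOCI = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")

#: Toy genome: three 10-Mb chromosomes.
TOY_CHROM_LENGTH = 10_000_000
TOY_CHROMS = {"chr1": TOY_CHROM_LENGTH, "chr2": TOY_CHROM_LENGTH, "chr3": TOY_CHROM_LENGTH}


class SpecError(ValueError):
    """An infeasible or inconsistent cohort specification."""


@dataclass(frozen=True)
class DriverGene:
    name: str
    chrom: str
    start: int
    end: int
    hotspot_pos: int
    hotspot_ref: str
    hotspot_alt: str
    hotspot_class: str
    hotspot_fraction: float


#: Emulates the recurrent in-frame glutamine deletion in the first driver gene.
DRIVER_A = DriverGene("ARID1A", "chr1", 1_000_000, 1_010_000, 1_002_334, "CAG", "-", "in_frame", 0.444)
#: Emulates the recurrent kinase-domain missense hotspot in the second driver gene.
DRIVER_B = DriverGene("PIK3CA", "chr3", 2_000_000, 2_010_000, 2_003_140, "A", "C", "missense", 0.478)


@dataclass(frozen=True)
class KataegisCluster:
    sample_index: int
    chrom: str
    n_mutations: int
    spacing: float  # mean gap between consecutive cluster mutations, bp


@dataclass(frozen=True)
class DepthModel:
    """Read-metric model; the *_fraction fields designate background variants
    that receive a metric engineered to fail one filter rule."""

    mean_depth: float = 732.0  # emulates the panel's average coverage
    dispersion: float = 12.0  # negative-binomial size parameter
    strand_bias_fraction: float = 0.03
    low_depth_fraction: float = 0.02
    low_vaf_fraction: float = 0.02
    low_quality_fraction: float = 0.02
    homopolymer_fraction: float = 0.02
    germline_fraction: float = 0.02
    snp_fraction: float = 0.02


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 55
    seed: int = 0
    true_signatures: np.ndarray | None = None  # 96 x 3, columns sum to 1
    subgroup_weights: dict = field(
        default_factory=lambda: {
            "ARID1A": (0.8, 0.1, 0.1),
            "Undetermined": (0.8, 0.1, 0.1),
            "PIK3CA": (0.1, 0.8, 0.1),
            "Double hit": (0.1, 0.1, 0.8),
        }
    )
    # Derived from the reported cohort: 27/55 and 23/55 gene prevalences
    # with 13 doubly mutated samples.
    subgroup_prevalence: dict = field(
        default_factory=lambda: {
            "ARID1A": 14 / 55,
            "PIK3CA": 10 / 55,
            "Double hit": 13 / 55,
            "Undetermined": 18 / 55,
        }
    )
    mutations_per_sample_mean: float = 200.0
    mutations_per_sample_dispersion: float = 10.0
    apobec_fraction: float = 1 / 6  # fraction of samples APOBEC-enriched
    apobec_forced_tcw_fraction: float = 0.30  # of their C>T/C>G mutations
    #: None selects the standard plan (clusters of 6/8/10 mutations at 400 bp
    #: spacing in the first three samples), trimmed to the cohort size.
    kataegis_plan: tuple[KataegisCluster, ...] | None = None
    msi_unstable_probs: tuple[float, ...] = (0.80, 0.07, 0.06, 0.04, 0.02, 0.01)
    msi_hypermutation_factor: float = 1.5  # count multiplier for MSI-H samples
    depth_model: DepthModel = field(default_factory=DepthModel)
    covered_bases_mean: float = 12_500_000.0
    covered_bases_sd: float = 500_000.0
    class_probs: dict = field(
        default_factory=lambda: {
            "silent": 0.29,
            "missense": 0.62,
            "nonsense": 0.05,
            "splice": 0.03,
            "intronic": 0.01,
        }
    )

    def resolved_kataegis_plan(self) -> tuple[KataegisCluster, ...]:
        if self.kataegis_plan is not None:
            return tuple(self.kataegis_plan)
        default = (
            KataegisCluster(0, "chr1", 6, 400.0),
            KataegisCluster(1, "chr2", 8, 400.0),
            KataegisCluster(2, "chr3", 10, 400.0),
        )
        return tuple(cl for cl in default if cl.sample_index < self.n_samples)

    def validate(self) -> None:
        prev = [self.subgroup_prevalence.get(g, 0.0) for g in SUBGROUPS]
        if any(p < 0 for p in prev) or abs(sum(prev) - 1.0) > 1e-9:
            raise SpecError("subgroup_prevalence must be non-negative and sum to 1")
        for g, w in self.subgroup_weights.items():
            if len(w) != 3 or min(w) < 0:
                raise SpecError(f"subgroup_weights[{g!r}] must be 3 non-negative values")
        if abs(sum(self.msi_unstable_probs) - 1.0) > 1e-9 or len(self.msi_unstable_probs) != 6:
            raise SpecError("msi_unstable_probs must be 6 probabilities summing to 1")
        if self.true_signatures is not None:
            S = np.asarray(self.true_signatures)
            if S.shape != (96, 3) or (S < 0).any() or np.any(np.abs(S.sum(0) - 1) > 1e-8):
                raise SpecError("true_signatures must be 96x3 with unit columns")
        for cl in self.resolved_kataegis_plan():
            if cl.chrom not in TOY_CHROMS:
                raise SpecError(f"kataegis cluster on unknown chromosome {cl.chrom}")
            if cl.n_mutations * cl.spacing * 2 > TOY_CHROMS[cl.chrom]:
                raise SpecError(f"kataegis cluster {cl} does not fit its chromosome")
            if not 0 <= cl.sample_index < self.n_samples:
                raise SpecError(f"kataegis cluster sample index {cl.sample_index} out of range")

    @classmethod
    def signature_study(cls, seed: int, **overrides) -> "CohortSpec":
        """The rank-selection experiment: 55 samples whose catalogs are pure
        three-signature mixtures at 200 mutations/sample, with the
        hypermutation and read-noise channels switched off so the spectra
        reflect the signature model alone."""
        base = dict(
            seed=seed,
            apobec_fraction=0.0,
            kataegis_plan=(),
            depth_model=DepthModel(
                strand_bias_fraction=0.0,
                low_depth_fraction=0.0,
                low_vaf_fraction=0.0,
                low_quality_fraction=0.0,
                homopolymer_fraction=0.0,
                germline_fraction=0.0,
                snp_fraction=0.0,
            ),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def kataegis_study(cls, seed: int, plan=(), n_samples: int = 10,
                       mutations_per_sample: float = 100.0, **overrides) -> "CohortSpec":
        """Kataegis detection conditions: cohort-wide mutation density kept
        below one per 10 kb (here 10 samples x ~100 mutations over 30 Mb)
        and no recurrent driver hotspots, so pooled intermutation distances
        have a clean background against which planted clusters stand out."""
        base = dict(
            seed=seed,
            n_samples=n_samples,
            mutations_per_sample_mean=mutations_per_sample,
            subgroup_prevalence={"ARID1A": 0.0, "PIK3CA": 0.0, "Double hit": 0.0,
                                 "Undetermined": 1.0},
            kataegis_plan=tuple(plan),
            apobec_fraction=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    sample_ids: list[str]
    subgroup: dict  # sample_id -> label
    mixture_weights: dict  # sample_id -> (w1, w2, w3)
    apobec_flag: dict  # sample_id -> bool
    kataegis_intervals: list  # (sample_id, chrom, start, end, n_mutations)
    msi_locus_calls: dict  # sample_id -> {locus: "stable"|"unstable"}
    msi_status: dict  # sample_id -> "MSS"|"MSI-H"|"indeterminate"
    covered_exonic_bases: dict  # sample_id -> float
    filter_expectations: list  # per emitted record: frozenset of failed rule names
    class_counts: dict  # variant_class -> injected count
    driver_mutated: dict  # sample_id -> set of driver gene names
    true_signatures: np.ndarray  # the 96 x 3 matrix actually used


#: Indices of the tCw motifs (T[C>T]A, T[C>T]T, T[C>G]A, T[C>G]T) and of all
#: C>T/C>G motifs, used to keep random signatures APOBEC-neutral.
_CT_CG = [SUBSTITUTIONS.index("C>T"), SUBSTITUTIONS.index("C>G")]
_CTCG_IDX = np.concatenate([np.arange(j * 16, (j + 1) * 16) for j in _CT_CG])
_TCW_IDX = np.array(
    [j * 16 + BASES.index("T") * 4 + BASES.index(b) for j in _CT_CG for b in "AT"]
)


def make_true_signatures(
    seed: int,
    min_pairwise_cosine_distance: float = 0.7,
    dominant_mass: float = 0.85,
    dominant_alpha: float = 0.08,
    rest_alpha: float = 0.05,
    max_tcw_share: float = 0.10,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Three sparse, well-separated ground-truth signatures (96 x 3).

    Each column concentrates ``dominant_mass`` of its probability on one
    substitution class — C>T, T>C and C>A respectively, emulating the
    class enrichments the subgroups exhibit — spread sparsely
    (Dirichlet ``dominant_alpha``) over that class's 16 motifs, with the
    remainder spread over the other 80 motifs.  Columns are re-drawn until
    every pairwise cosine similarity is at most
    ``1 - min_pairwise_cosine_distance`` and, so that baseline samples stay
    APOBEC-negative, until at most ``max_tcw_share`` of each column's
    C>T/C>G mass sits in tCw motifs (the random expectation is 1/8).
    """
    if not 0 < min_pairwise_cosine_distance < 1:
        raise ValueError("min_pairwise_cosine_distance must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    dominant_classes = ("C>T", "T>C", "C>A")
    max_cos = 1.0 - min_pairwise_cosine_distance
    for _ in range(max_attempts):
        cols = []
        for sub in dominant_classes:
            j = SUBSTITUTIONS.index(sub)
            for _ in range(max_attempts):
                col = np.zeros(96)
                col[j * 16 : (j + 1) * 16] = rng.dirichlet([dominant_alpha] * 16) * dominant_mass
                rest = np.concatenate([np.arange(0, j * 16), np.arange((j + 1) * 16, 96)])
                col[rest] = rng.dirichlet([rest_alpha] * 80) * (1.0 - dominant_mass)
                ctcg = col[_CTCG_IDX].sum()
                if ctcg == 0 or col[_TCW_IDX].sum() / ctcg <= max_tcw_share:
                    break
            else:
                raise SpecError("could not draw an APOBEC-neutral signature column")
            cols.append(col)
        S = np.column_stack(cols)
        norms = np.linalg.norm(S, axis=0)
        G = (S.T @ S) / np.outer(norms, norms)
        if max(G[0, 1], G[0, 2], G[1, 2]) <= max_cos:
            return S / S.sum(0)
    raise SpecError(
        f"could not draw signatures with pairwise cosine <= {max_cos:.3f} "
        f"in {max_attempts} attempts"
    )


def synthetic_reference_set(seed: int = 7, n_signatures: int = 5):
    """A small synthetic COSMIC-like reference set (clearly a stand-in).

    Columns imitate the *shapes* of well-known signature families —
    an NpCpG-peaked C>T ageing-like column, a tCw-peaked APOBEC-like
    column, a flat clock-like column, a C>T-heavy MMR-like column and a
    T>G-peaked column — without reproducing any real COSMIC values.
    Signature names carry a ``syn`` prefix to mark them synthetic.
    """
    from .io_formats import ReferenceSignatureSet
    from .motifs import MOTIF_INDEX

    rng = np.random.default_rng(seed)
    cols = []
    names = ["synSBS1", "synSBS2", "synSBS5", "synSBS6", "synSBS13"][:n_signatures]
    builders = {
        "synSBS1": [(f"{f}[C>T]G", 0.20) for f in "ACGT"],
        "synSBS2": [(f"T[C>T]{t}", 0.38) for t in "AT"],
        "synSBS5": [],  # flat
        "synSBS6": [(f"G[C>T]{t}", 0.18) for t in "ACGT"],
        "synSBS13": [(f"T[C>G]{t}", 0.38) for t in "AT"],
    }
    for name in names:
        col = rng.dirichlet([0.5] * 96) * 0.25 if name != "synSBS5" else rng.dirichlet([5.0] * 96)
        for motif, mass in builders[name]:
            col[MOTIF_INDEX[motif]] += mass
        cols.append(col / col.sum())
    return ReferenceSignatureSet(names=names, matrix=np.column_stack(cols))


# -- helpers ----------------------------------------------------------------

_HOMOPOLYMER_RE = re.compile(r"A{6,}|C{6,}|G{6,}|T{6,}")


def _expected_homopolymer(context: str, window: int = 5) -> bool:
    centre = len(context) // 2
    for m in _HOMOPOLYMER_RE.finditer(context):
        if m.start() <= centre + window and m.end() - 1 >= centre - window:
            return True
    return False


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _random_flanks(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, n)])


def _context_for_motif(rng: np.random.Generator, motif: str, purine_strand: bool) -> tuple[str, str, str, str]:
    """Synthesize (ref, alt, context41) for a motif, optionally reported on
    the purine strand.  Returns (ref, alt, context, trinuc_as_emitted)."""
    key = parse_motif(motif)
    ref, alt = key.substitution.split(">")
    tri = key.five_prime + ref + key.three_prime
    if purine_strand:
        ref, alt, tri = revcomp(ref), revcomp(alt), revcomp(tri)
    left = _random_flanks(rng, CONTEXT_FLANK - 1)
    right = _random_flanks(rng, CONTEXT_FLANK - 1)
    context = left + tri + right
    return ref, alt, context, tri


def _avoid_homopolymer(context: str, rng: np.random.Generator) -> str:
    """Break any >=6 run near the centre so the flag stays a designed event."""
    while _expected_homopolymer(context):
        chars = list(context)
        m = _HOMOPOLYMER_RE.search(context)
        i = m.start() + 3
        if abs(i - CONTEXT_FLANK) <= 1:
            i = m.start() if abs(m.start() - CONTEXT_FLANK) > 1 else m.end() - 1
        others = [b for b in BASES if b != chars[i]]
        chars[i] = others[rng.integers(0, 3)]
        context = "".join(chars)
    return context


def _inject_homopolymer(context: str, rng: np.random.Generator) -> str:
    """Place a 6-base run overlapping the +-5 window, away from the centre triplet."""
    base = BASES[rng.integers(0, 4)]
    start = CONTEXT_FLANK + 2  # occupies offsets +2..+7, overlapping the +-5 window
    chars = list(context)
    chars[start : start + 6] = [base] * 6
    return "".join(chars)


def _clean_metrics(rng: np.random.Generator, dm: DepthModel) -> dict:
    depth = max(_neg_binomial(rng, dm.mean_depth, dm.dispersion), 150)
    vaf_true = rng.uniform(0.15, 0.6)
    alt = int(rng.binomial(depth, vaf_true))
    alt = min(max(alt, int(np.ceil(0.06 * depth))), depth)
    ref = depth - alt
    alt_fwd = int(rng.binomial(alt, 0.5))
    ref_fwd = int(rng.binomial(ref, 0.5))
    return {
        "depth": depth,
        "alt_fwd": alt_fwd,
        "alt_rev": alt - alt_fwd,
        "ref_fwd": ref_fwd,
        "ref_rev": ref - ref_fwd,
        "vaf": alt / depth,
        "phred_quality": float(rng.uniform(150, 400)),
    }


def _strand_biased_metrics(rng: np.random.Generator) -> dict:
    # All alt reads on one strand at high depth: Fisher PS far above 60.
    depth = 600
    alt = 150
    ref = depth - alt
    ref_fwd = int(rng.binomial(ref, 0.5))
    fwd = bool(rng.integers(0, 2))
    return {
        "depth": depth,
        "alt_fwd": alt if fwd else 0,
        "alt_rev": 0 if fwd else alt,
        "ref_fwd": ref_fwd,
        "ref_rev": ref - ref_fwd,
        "vaf": alt / depth,
        "phred_quality": float(rng.uniform(150, 400)),
    }


# -- main entry point -------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> tuple[list[VariantRecord], GroundTruth]:
    """Generate a cohort table and its ground truth (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    signatures = (
        np.asarray(spec.true_signatures, dtype=float)
        if spec.true_signatures is not None
        else make_true_signatures(int(rng.integers(0, 2**31 - 1)))
    )
    dm = spec.depth_model
    sample_ids = [f"S{i+1:03d}" for i in range(spec.n_samples)]
    labels = rng.choice(
        SUBGROUPS, size=spec.n_samples, p=[spec.subgroup_prevalence[g] for g in SUBGROUPS]
    )
    apobec = np.zeros(spec.n_samples, dtype=bool)
    n_apobec = int(round(spec.apobec_fraction * spec.n_samples))
    if n_apobec:
        apobec[rng.choice(spec.n_samples, size=n_apobec, replace=False)] = True

    clusters_by_sample: dict[int, list[KataegisCluster]] = {}
    for cl in spec.resolved_kataegis_plan():
        clusters_by_sample.setdefault(cl.sample_index, []).append(cl)

    records: list[VariantRecord] = []
    expectations: list[frozenset] = []
    truth = GroundTruth(
        sample_ids=sample_ids,
        subgroup={},
        mixture_weights={},
        apobec_flag={},
        kataegis_intervals=[],
        msi_locus_calls={},
        msi_status={},
        covered_exonic_bases={},
        filter_expectations=expectations,
        class_counts={},
        driver_mutated={},
        true_signatures=signatures,
    )
    class_list = list(spec.class_probs)
    class_p = np.array([spec.class_probs[c] for c in class_list], dtype=float)
    class_p /= class_p.sum()
    driver_regions = [(d.chrom, d.start, d.end) for d in (DRIVER_A, DRIVER_B)]
    chrom_names = list(TOY_CHROMS)

    for si, sid in enumerate(sample_ids):
        label = str(labels[si])
        truth.subgroup[sid] = label
        weights = np.asarray(spec.subgroup_weights[label], dtype=float)
        weights = weights / weights.sum()
        truth.mixture_weights[sid] = tuple(weights)
        truth.apobec_flag[sid] = bool(apobec[si])
        truth.driver_mutated[sid] = set()

        # MSI profile first, since MSI-H boosts the mutation count.
        n_unstable = int(rng.choice(6, p=spec.msi_unstable_probs))
        unstable = set(rng.choice(MSI_LOCI, size=n_unstable, replace=False)) if n_unstable else set()
        truth.msi_locus_calls[sid] = {
            loc: ("unstable" if loc in unstable else "stable") for loc in MSI_LOCI
        }
        truth.msi_status[sid] = (
            "MSI-H" if n_unstable >= 3 else ("MSS" if n_unstable == 0 else "indeterminate")
        )
        truth.covered_exonic_bases[sid] = float(
            max(rng.normal(spec.covered_bases_mean, spec.covered_bases_sd), 1e6)
        )

        sample_records: list[VariantRecord] = []
        sample_expect: list[dict] = []  # partial expectations; depth rules resolved later

        def emit(rec: VariantRecord, expect: dict) -> None:
            sample_records.append(rec)
            sample_expect.append(expect)
            truth.class_counts[rec.variant_class] = truth.class_counts.get(rec.variant_class, 0) + 1

        # --- driver mutations ------------------------------------------------
        for driver, hit in ((DRIVER_A, label in ("ARID1A", "Double hit")),
                            (DRIVER_B, label in ("PIK3CA", "Double hit"))):
            if not hit:
                continue
            truth.driver_mutated[sid].add(driver.name)
            metrics = _clean_metrics(rng, dm)
            if rng.uniform() < driver.hotspot_fraction:
                pos, ref, alt, vclass = (
                    driver.hotspot_pos, driver.hotspot_ref, driver.hotspot_alt, driver.hotspot_class,
                )
                if len(ref) == 1 and len(alt) == 1:
                    context = _random_flanks(rng, CONTEXT_FLANK) + ref + _random_flanks(rng, CONTEXT_FLANK)
                else:
                    context = _random_flanks(rng, CONTEXT_FLANK) + ref[0] + _random_flanks(rng, CONTEXT_FLANK)
            else:
                pos = int(rng.integers(driver.start, driver.end + 1))
                motif = MOTIF_ORDER[int(rng.integers(0, 96))]
                ref, alt, context, _ = _context_for_motif(rng, motif, bool(rng.integers(0, 2)))
                vclass = ("missense", "nonsense")[int(rng.integers(0, 2))]
            context = _avoid_homopolymer(context, rng)
            rec = VariantRecord(
                sample_id=sid, chrom=driver.chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                gene=driver.name, variant_class=vclass, context41=context, **metrics,
            )
            emit(rec, {"base": set()})

        # --- background mutations -------------------------------------------
        n_mut = _neg_binomial(
            rng, spec.mutations_per_sample_mean, spec.mutations_per_sample_dispersion
        )
        if truth.msi_status[sid] == "MSI-H":
            n_mut = int(round(n_mut * spec.msi_hypermutation_factor))
        mixture = signatures @ weights
        motif_idx = rng.choice(96, size=n_mut, p=mixture)
        for mi in motif_idx:
            motif = MOTIF_ORDER[int(mi)]
            key = parse_motif(motif)
            forced_tcw = False
            if (
                truth.apobec_flag[sid]
                and key.substitution in ("C>T", "C>G")
                and rng.uniform() < spec.apobec_forced_tcw_fraction
            ):
                motif = f"T[{key.substitution}]{'A' if rng.integers(0, 2) else 'T'}"
                forced_tcw = True
            ref, alt, context, _ = _context_for_motif(rng, motif, bool(rng.integers(0, 2)))
            context = _avoid_homopolymer(context, rng)
            # uniform placement outside driver regions
            while True:
                chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                pos = int(rng.integers(CONTEXT_FLANK + 1, TOY_CHROMS[chrom] - CONTEXT_FLANK))
                if not any(c == chrom and s <= pos <= e for c, s, e in driver_regions):
                    break
            gene = f"G{chrom[3:]}_{pos // 100_000:03d}"
            vclass = class_list[int(rng.choice(len(class_list), p=class_p))]
            metrics = _clean_metrics(rng, dm)
            expect: set[str] = set()
            germline = snp = False
            u = rng.uniform()
            # mutually exclusive noise channels, applied to background only
            cum = 0.0
            if u < (cum := cum + dm.strand_bias_fraction):
                metrics = _strand_biased_metrics(rng)
                expect.add("strand_bias")
            elif u < (cum := cum + dm.low_depth_fraction):
                depth = int(rng.integers(20, 100))
                alt_n = max(int(round(depth * rng.uniform(0.15, 0.5))), 1)
                af = int(rng.binomial(alt_n, 0.5))
                rf = int(rng.binomial(depth - alt_n, 0.5))
                metrics = {
                    "depth": depth, "alt_fwd": af, "alt_rev": alt_n - af,
                    "ref_fwd": rf, "ref_rev": depth - alt_n - rf,
                    "vaf": alt_n / depth, "phred_quality": float(rng.uniform(150, 400)),
                }
                expect.add("min_depth")
            elif u < (cum := cum + dm.low_vaf_fraction):
                metrics = dict(metrics)
                depth = metrics["depth"]
                alt_n = max(int(depth * rng.uniform(0.005, 0.045)), 0)
                af = int(rng.binomial(alt_n, 0.5)) if alt_n else 0
                rf = int(rng.binomial(depth - alt_n, 0.5))
                metrics.update(
                    alt_fwd=af, alt_rev=alt_n - af, ref_fwd=rf,
                    ref_rev=depth - alt_n - rf, vaf=alt_n / depth,
                )
                expect.add("min_vaf")
            elif u < (cum := cum + dm.low_quality_fraction):
                metrics = dict(metrics)
                metrics["phred_quality"] = float(rng.uniform(10, 99))
                expect.add("min_phred_quality")
            elif u < (cum := cum + dm.homopolymer_fraction):
                context = _inject_homopolymer(context, rng)
                expect.add("homopolymer")
            elif u < (cum := cum + dm.germline_fraction):
                germline = True
                expect.add("germline")
            elif u < (cum := cum + dm.snp_fraction):
                snp = True
                expect.add("common_snp")
            if vclass == "intronic":
                expect.add("variant_class")
            if forced_tcw:
                pass  # bookkeeping only; tCw forcing leaves metrics clean
            rec = VariantRecord(
                sample_id=sid, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                gene=gene, variant_class=vclass, context41=context,
                is_putative_germline=germline, is_common_snp=snp, **metrics,
            )
            emit(rec, {"base": expect})

        # --- planted kataegis clusters ---------------------------------------
        for cl in clusters_by_sample.get(si, ()):
            gaps = rng.uniform(0.5, 1.5, cl.n_mutations - 1) * cl.spacing
            span = float(gaps.sum())
            start = int(
                rng.integers(CONTEXT_FLANK + 1, TOY_CHROMS[cl.chrom] - int(span) - CONTEXT_FLANK)
            )
            positions = start + np.concatenate([[0.0], np.cumsum(gaps)]).astype(int)
            for pos in positions:
                sub = ("C>T", "C>G")[int(rng.integers(0, 2))]
                motif = f"T[{sub}]{'A' if rng.integers(0, 2) else 'T'}"
                ref, alt, context, _ = _context_for_motif(rng, motif, bool(rng.integers(0, 2)))
                context = _avoid_homopolymer(context, rng)
                rec = VariantRecord(
                    sample_id=sid, chrom=cl.chrom, pos=int(pos), ref_allele=ref,
                    alt_allele=alt, gene=f"G{cl.chrom[3:]}_{int(pos) // 100_000:03d}",
                    variant_class="missense", context41=context,
                    **_clean_metrics(rng, dm),
                )
                emit(rec, {"base": set()})
            truth.kataegis_intervals.append(
                (sid, cl.chrom, int(positions[0]), int(positions[-1]), cl.n_mutations)
            )

        # Resolve depth-relative expectations now the sample is complete.
        med = float(np.median([r.depth for r in sample_records]))
        for rec, ex in zip(sample_records, sample_expect):
            failed = set(ex["base"])
            if rec.depth < 100:
                failed.add("min_depth")
            if rec.depth < 0.10 * med:
                failed.add("median_depth_fraction")
            if rec.vaf < 0.05:
                failed.add("min_vaf")
            if rec.phred_quality < 100:
                failed.add("min_phred_quality")
            sb = _strand_bias_phred(rec.ref_fwd, rec.ref_rev, rec.alt_fwd, rec.alt_rev)
            if sb.phred_score > 60.0:
                failed.add("strand_bias")
            if _expected_homopolymer(rec.context41):
                failed.add("homopolymer")
            if rec.is_putative_germline:
                failed.add("germline")
            if rec.is_common_snp:
                failed.add("common_snp")
            if rec.variant_class == "intronic":
                failed.add("variant_class")
            expectations.append(frozenset(failed))
        records.extend(sample_records)

    return records, truth
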