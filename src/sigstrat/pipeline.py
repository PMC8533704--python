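"""End-to-end orchestration: simulate/ingest -> filter -> spectra ->
de novo + supervised signatures -> hypermutation -> instability -> cohort
statistics, with a reproducibility manifest.

Every stage writes plain TSV/JSON outputs into the run directory; files
are written atomically (temp file + rename) and a manifest records the
seed, a config hash and per-stage record counts.  A single master seed
drives deterministic per-stage streams, so identical config + seed give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    assign_subgroups,
    interactions_frame,
    pairwise_interactions,
    prevalence_table,
    union_cooccurrence,
)
from .denovo_signatures import MutationalSignatureModel
from .hypermutation import KataegisConfig, apobec_by_sample, call_kataegis
from .instability import classify_msi, compute_tml
from .io_formats import (
    read_signature_matrix,
    read_variant_table,
    write_signature_matrix,
    write_variant_table,
)
from .spectrum import build_spectra, class_tally, spectra_matrix, titv_summary
from .supervised_signatures import exposures_frame, subgroup_exposures
from .synthetic_cohort import MSI_LOCI, CohortSpec, generate_cohort
from .variant_filter import FilterConfig, apply_filters, verdicts_to_frame


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    output_dir: str = "sigstrat_run"
    seed: int = 17
    variants_path: str | None = None  # ingest instead of simulate when set
    dialect: str = "maf_like"
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    filters: dict = field(default_factory=dict)  # FilterConfig overrides
    nmf_ranks: tuple[int, int] = (1, 4)
    nmf_restarts: int = 500
    reference_signatures: str | None = None  # path; synthetic set when None
    msi_calls: str | None = None  # TSV path; simulated truth when None
    coverage: str | None = None  # TSV path; simulated truth when None
    tml_threshold: float = 20.0
    kataegis: dict = field(default_factory=dict)  # KataegisConfig overrides
    gene_a: str = "ARID1A"
    gene_b: str = "PIK3CA"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "nmf_ranks" in raw:
            raw["nmf_ranks"] = tuple(raw["nmf_ranks"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=kwargs.pop("index", False), **kwargs)
    tmp.replace(path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    On a stage failure, outputs written so far are preserved and a
    ``failed/<stage>`` marker is left in the run directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (config.variants_path, config.reference_signatures, config.msi_calls, config.coverage):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    manifest: dict = {
        "tool": "sigstrat",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    streams = np.random.SeedSequence(config.seed).generate_state(8)
    stage = "setup"
    truth = None
    try:
        # -- 1. simulate or ingest ------------------------------------------
        stage = "cohort"
        t0 = time.time()
        if config.variants_path is None:
            spec = CohortSpec(seed=int(streams[0] % (2**31 - 1)), **config.cohort)
            records, truth = generate_cohort(spec)
            write_variant_table(records, out / "cohort.maf.tsv")
            _write_truth(truth, out / "truth.json")
        else:
            records = read_variant_table(config.variants_path, dialect=config.dialect)
        manifest["stages"][stage] = {"n_records": len(records), "seconds": round(time.time() - t0, 2)}

        # -- 2. filter -------------------------------------------------------
        stage = "filter"
        t0 = time.time()
        fconf = FilterConfig(**config.filters)
        passed, verdicts = apply_filters(records, fconf)
        write_variant_table(passed, out / "passed.maf.tsv")
        _atomic_write(verdicts_to_frame(verdicts), out / "verdicts.tsv")
        manifest["stages"][stage] = {
            "n_in": len(records),
            "n_passed": len(passed),
            "seconds": round(time.time() - t0, 2),
        }

        # -- 3. spectra ------------------------------------------------------
        stage = "spectrum"
        t0 = time.time()
        spectra = build_spectra(passed)
        V = spectra_matrix(spectra)
        _atomic_write(V, out / "spectra.tsv", index=True)
        ti, tv = titv_summary(passed)
        tally = class_tally(passed)
        pd.DataFrame([{"transitions": ti, "transversions": tv, **tally}]).pipe(
            _atomic_write, out / "substitution_summary.tsv"
        )
        manifest["stages"][stage] = {
            "n_samples": V.shape[1],
            "n_snvs": int(V.to_numpy().sum()),
            "seconds": round(time.time() - t0, 2),
        }

        # -- 4. de novo signatures ------------------------------------------
        stage = "denovo"
        t0 = time.time()
        model = MutationalSignatureModel(V)
        selection = model.select_rank(
            rank_range=config.nmf_ranks,
            n_restarts=config.nmf_restarts,
            seed=int(streams[1] % (2**31 - 1)),
        )
        _atomic_write(selection.summary(), out / "rank_statistics.tsv")
        best = selection.best_runs[selection.chosen_rank]
        from .denovo_signatures import SignatureResults

        results = SignatureResults(model, best)
        _atomic_write(results.signatures_frame(), out / "signatures.tsv", index=True)
        _atomic_write(results.exposures_frame(), out / "exposures.tsv", index=True)
        manifest["stages"][stage] = {
            "chosen_rank": selection.chosen_rank,
            "explained_variance": round(results.explained_variance, 3),
            "seconds": round(time.time() - t0, 2),
        }

        # -- 5. supervised exposures ----------------------------------------
        stage = "supervised"
        t0 = time.time()
        if config.reference_signatures:
            refs = read_signature_matrix(config.reference_signatures)
        else:
            from .synthetic_cohort import synthetic_reference_set

            refs = synthetic_reference_set(seed=int(streams[2] % (2**31 - 1)))
            write_signature_matrix(refs, out / "reference_signatures.synthetic.tsv")
        labels = assign_subgroups(passed, gene_a=config.gene_a, gene_b=config.gene_b)
        label_map = {l.sample_id: l.label for l in labels}
        groups, samples = subgroup_exposures(spectra, label_map, refs)
        _atomic_write(exposures_frame(groups, fractions=True), out / "subgroup_exposures.tsv", index=True)
        _atomic_write(exposures_frame(samples, fractions=True), out / "sample_exposures.tsv", index=True)
        manifest["stages"][stage] = {
            "n_references": len(refs.names),
            "n_subgroups": len(groups),
            "seconds": round(time.time() - t0, 2),
        }

        # -- 6. hypermutation -----------------------------------------------
        stage = "hypermutation"
        t0 = time.time()
        kconf = KataegisConfig(**config.kataegis)
        foci = call_kataegis(passed, kconf)
        _atomic_write(
            pd.DataFrame(
                [
                    {
                        "sample_id": s.sample_id,
                        "chrom": s.chrom,
                        "start": s.start,
                        "end": s.end,
                        "n_mutations": s.n_mutations,
                        "mean_imd": s.mean_distance,
                        "is_kataegis": int(s.is_kataegis),
                    }
                    for s in foci
                ],
                columns=["sample_id", "chrom", "start", "end", "n_mutations", "mean_imd", "is_kataegis"],
            ),
            out / "kataegis.tsv",
        )
        apo = apobec_by_sample(passed)
        _atomic_write(
            pd.DataFrame(
                {
                    "sample_id": [a.sample_id for a in apo],
                    "mut_tcw": [a.mut_tcw for a in apo],
                    "mut_c": [a.mut_c for a in apo],
                    "background_tcw": [a.background_tcw for a in apo],
                    "background_c": [a.background_c for a in apo],
                    "enrichment": [a.enrichment for a in apo],
                    "is_positive": [int(a.is_positive) for a in apo],
                }
            ),
            out / "apobec.tsv",
        )
        manifest["stages"][stage] = {
            "n_kataegis_foci": len(foci),
            "n_apobec_positive": sum(a.is_positive for a in apo),
            "seconds": round(time.time() - t0, 2),
        }

        # -- 7. instability --------------------------------------------------
        stage = "instability"
        t0 = time.time()
        coverage = _load_coverage(config, truth)
        msi_calls = _load_msi(config, truth)
        counts: dict[str, int] = {}
        for rec in passed:
            counts[rec.sample_id] = counts.get(rec.sample_id, 0) + 1
        tml_rows = []
        for sid in sorted(counts):
            if sid not in coverage:
                raise ValueError(f"no coverage entry for sample {sid}")
            res = compute_tml(counts[sid], coverage[sid], sample_id=sid, threshold=config.tml_threshold)
            tml_rows.append(
                {
                    "sample_id": sid,
                    "n_mutations": res.somatic_mutation_count,
                    "covered_exonic_bases": res.covered_exonic_bases,
                    "tml": res.tml,
                    "status": res.status,
                }
            )
        _atomic_write(pd.DataFrame(tml_rows), out / "tml.tsv")
        msi_rows = []
        for sid, calls in sorted(msi_calls.items()):
            res = classify_msi(calls, sample_id=sid)
            msi_rows.append(
                {"sample_id": sid, **res.locus_calls, "n_unstable": res.n_unstable, "status": res.status}
            )
        _atomic_write(pd.DataFrame(msi_rows), out / "msi.tsv")
        manifest["stages"][stage] = {
            "n_tml_high": sum(r["status"] == "high" for r in tml_rows),
            "n_msi_h": sum(r["status"] == "MSI-H" for r in msi_rows),
            "seconds": round(time.time() - t0, 2),
        }

        # -- 8. cohort statistics -------------------------------------------
        stage = "cohort_stats"
        t0 = time.time()
        _atomic_write(
            pd.DataFrame({"sample_id": [l.sample_id for l in labels], "subgroup": [l.label for l in labels]}),
            out / "subgroups.tsv",
        )
        prev = prevalence_table(passed, labels)
        _atomic_write(prev["gene_prevalence"], out / "prevalence.tsv")
        inter = pairwise_interactions(passed)
        _atomic_write(interactions_frame(inter), out / "interactions.tsv")
        union = union_cooccurrence(passed, config.gene_a, config.gene_b)
        summary = {
            "n_samples": prev["n_samples"],
            "subgroup_counts": {k: v[0] for k, v in prev.get("subgroup_counts", {}).items()},
            "driver_union": union,
            "n_cooccurring": sum(r.direction == "co-occurring" for r in inter),
            "n_mutually_exclusive": sum(r.direction == "mutually exclusive" for r in inter),
        }
        _atomic_json(summary, out / "cohort_summary.json")
        manifest["stages"][stage] = {
            "n_pairs_tested": len(inter),
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        marker_dir = out / "failed"
        marker_dir.mkdir(exist_ok=True)
        (marker_dir / stage).write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(stage, exc) from exc
    _atomic_json(manifest, out / "manifest.json")
    return out


def _atomic_json(obj, path: Path) -> None:
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(obj, indent=2, default=str) + "\n")
    tmp.replace(path)


def _write_truth(truth, path: Path) -> None:
    payload = {
        "subgroup": truth.subgroup,
        "mixture_weights": {k: list(v) for k, v in truth.mixture_weights.items()},
        "apobec_flag": truth.apobec_flag,
        "kataegis_intervals": truth.kataegis_intervals,
        "msi_status": truth.msi_status,
        "msi_locus_calls": truth.msi_locus_calls,
        "covered_exonic_bases": truth.covered_exonic_bases,
        "class_counts": truth.class_counts,
        "driver_mutated": {k: sorted(v) for k, v in truth.driver_mutated.items()},
        "filter_expectations": [sorted(s) for s in truth.filter_expectations],
    }
    _atomic_json(payload, path)


def _load_coverage(config: PipelineConfig, truth) -> dict:
    if config.coverage:
        df = pd.read_csv(config.coverage, sep="\t")
        return dict(zip(df["sample_id"].astype(str), df["covered_exonic_bases"].astype(float)))
    if truth is not None:
        return dict(truth.covered_exonic_bases)
    raise ValueError("instability stage needs a coverage table when ingesting external variants")


def _load_msi(config: PipelineConfig, truth) -> dict:
    if config.msi_calls:
        df = pd.read_csv(config.msi_calls, sep="\t")
        return {
            str(row["sample_id"]): {loc: str(row[loc]) for loc in MSI_LOCI}
            for _, row in df.iterrows()
        }
    if truth is not None:
        return dict(truth.msi_locus_calls)
    raise ValueError("instability stage needs MSI locus calls when ingesting external variants")
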