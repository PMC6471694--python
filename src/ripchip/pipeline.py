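"""End-to-end pipeline: sites -> variables -> enrichment -> evaluation
-> SVM -> shuffling, with a stable output layout and a manifest.

A run directory contains::

    bs_matrices/        BS/dBS TSVs (when built from sequences or simulated)
    variables.tsv       gene x 19 variable table (+ sidecar JSON)
    enrichment.tsv      per-gene SAM d, q, call
    up_genes.txt / low_genes.txt
    auc_table.tsv       per-variable AUC and rank-sum p
    svm_matrix.tsv      pairwise LOOCV AUC matrix
    shuffle/*.json      per-scheme shuffling results
    manifest.json       config hash, seed, sha256 of every output
    run.log             timings and stage messages (not hashed)

All data outputs are deterministic functions of config + seed; the
manifest lists their digests so two runs can be compared byte-wise.
run.log carries wall-clock timings and is excluded from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import enrichment as enr
from . import evaluation as ev
from . import expression as expr
from . import models, sequences, shuffling, synthetic
from . import variables as vars_mod

logger = logging.getLogger("ripchip.pipeline")


class ValidationError(ValueError):
    """Config or input validation failure (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are kept."""


@dataclass
class RunConfig:
    """Everything a full run needs.

    Either ``synthetic`` is true (a dataset is simulated from the
    embedded SyntheticConfig fields) or the input paths must point to
    existing files.
    """

    seed: int = 0
    q_threshold: float = 0.05
    top_k: int = 50
    n_sim: int = 1000
    n_perm: int = 200
    svm_cost: float = 1.0
    paired_sam: bool = False
    strict_exceedance: bool = False
    svm_log_transform: bool = True
    shuffle_variables: tuple[str, ...] = ("F6", "F4d")
    svm_variables: tuple[str, ...] | None = None  # None = all 19
    # synthetic-mode knobs
    synthetic: bool = True
    mode: str = "ago2_like"
    n_genes: int = 2000
    n_mirnas: int = 50
    effect_beta: float | None = None
    # real-data inputs (used when synthetic=False)
    utr_fasta: str | None = None
    cds_fasta: str | None = None
    seeds_file: str | None = None
    expression_tsv: str | None = None
    samples_tsv: str | None = None
    mirna_profile_tsv: str | None = None
    in_sample: str | None = None  # sample id providing the IN mRNA profile

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        for key in ("shuffle_variables", "svm_variables"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        if self.n_sim <= 0 or self.n_perm < 1 or self.top_k <= 0:
            raise ValidationError("n_sim, n_perm and top_k must be positive")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must be in (0, 1)")
        if not self.synthetic:
            required = ("expression_tsv", "samples_tsv", "mirna_profile_tsv")
            for name in required:
                value = getattr(self, name)
                if value is None:
                    raise ValidationError(f"missing input path: {name}")
                if not Path(value).exists():
                    raise ValidationError(f"input file not found: {name}={value}")
            for name in ("utr_fasta", "cds_fasta", "seeds_file"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    raise ValidationError(f"input file not found: {name}={value}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def setup_logging(log_file: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and return the run directory.

    Any stage failure raises :class:`StageError` naming the stage;
    outputs written so far and run.log are left in place.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")
    outputs: list[Path] = []
    stage = "setup"
    t0 = time.time()
    try:
        # ---- stage: simulate / load ------------------------------------
        stage = "simulate" if config.synthetic else "load"
        t = time.time()
        if config.synthetic:
            ds = synthetic.generate_dataset(synthetic.SyntheticConfig(
                n_genes=config.n_genes, n_mirnas=config.n_mirnas, mode=config.mode,
                effect_beta=config.effect_beta, top_k=config.top_k, seed=config.seed,
            ))
            mirna_profile = ds.mirna_profile
            mrna_profile = ds.mrna_profile
            bs_utr, bs_cds = ds.bs_utr, ds.bs_cds
            dbs_utr, dbs_cds = ds.dbs_utr, ds.dbs_cds
            lengths = ds.lengths
            expression = ds.expression
            truth = out / "true_labels.tsv"
            ds.true_labels.rename("label").to_csv(truth, sep="\t", index_label="gene_id")
            outputs.append(truth)
        else:
            expression = expr.ExpressionMatrix.read_tsv(
                config.expression_tsv, config.samples_tsv)
            _check_roles(expression)
            mirna_profile = pd.read_csv(config.mirna_profile_tsv, sep="\t",
                                        index_col=0).iloc[:, 0]
            bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = _sites_from_sequences(config)
            mrna_profile = None  # set after normalization below
        logger.info("stage %s done in %.1fs", stage, time.time() - t)

        # ---- stage: sites output ---------------------------------------
        stage = "sites"
        t = time.time()
        bs_dir = out / "bs_matrices"
        bs_dir.mkdir(exist_ok=True)
        for name, m in (("bs_utr3", bs_utr), ("bs_cds", bs_cds),
                        ("dbs_utr3", dbs_utr), ("dbs_cds", dbs_cds)):
            m.to_tsv(bs_dir / f"{name}.tsv")
            outputs += [bs_dir / f"{name}.tsv", bs_dir / f"{name}.tsv.json"]
        logger.info("stage sites done in %.1fs", time.time() - t)

        # ---- stage: preprocess + enrichment ----------------------------
        stage = "enrich"
        t = time.time()
        _check_roles(expression)
        normalized = expr.quantile_normalize(expression)
        if mrna_profile is None:
            in_ids = [s.sample_id for s in normalized.samples if s.role == expr.ROLE_IN]
            if not in_ids:
                raise ValidationError("expression matrix has no IN samples")
            sample_id = config.in_sample or in_ids[0]
            mrna_profile = normalized.column(sample_id)
        labels_obj = enr.sam_enrichment(
            normalized, n_perm=config.n_perm, q_threshold=config.q_threshold,
            seed=config.seed, paired=config.paired_sam,
        )
        labels_obj.to_tsv(out / "enrichment.tsv")
        outputs.append(out / "enrichment.tsv")
        for call, fname in ((enr.CALL_UP, "up_genes.txt"), (enr.CALL_LOW, "low_genes.txt")):
            (out / fname).write_text("".join(g + "\n" for g in labels_obj.genes(call)))
            outputs.append(out / fname)
        calls = labels_obj.calls
        n_up, n_low = len(labels_obj.genes("UP")), len(labels_obj.genes("LOW"))
        logger.info("stage enrich done in %.1fs (%d UP, %d LOW)",
                    time.time() - t, n_up, n_low)
        if min(n_up, n_low) < 2:
            raise StageError("enrich: fewer than two genes per class called")

        # ---- stage: variables ------------------------------------------
        stage = "variables"
        t = time.time()
        vtable = vars_mod.compute_variables(
            mirna_profile, mrna_profile, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
            mirna_subset=min(config.top_k, len(mirna_profile)),
        )
        vtable.to_tsv(out / "variables.tsv")
        outputs += [out / "variables.tsv", out / "variables.tsv.json"]
        logger.info("stage variables done in %.1fs", time.time() - t)

        # ---- stage: evaluate -------------------------------------------
        stage = "evaluate"
        t = time.time()
        auc_table = ev.variable_auc_table(vtable, calls)
        auc_table.to_csv(out / "auc_table.tsv", sep="\t", index=False)
        outputs.append(out / "auc_table.tsv")
        logger.info("stage evaluate done in %.1fs", time.time() - t)

        # ---- stage: svm -------------------------------------------------
        stage = "svm"
        t = time.time()
        svm_vars = list(config.svm_variables) if config.svm_variables else None
        svm_matrix = models.pairwise_auc_matrix(
            vtable, calls, cost=config.svm_cost, variables=svm_vars,
            log_transform=config.svm_log_transform,
        )
        svm_matrix.to_csv(out / "svm_matrix.tsv", sep="\t", index_label="variable")
        outputs.append(out / "svm_matrix.tsv")
        logger.info("stage svm done in %.1fs", time.time() - t)

        # ---- stage: shuffle --------------------------------------------
        stage = "shuffle"
        t = time.time()
        shuffle_dir = out / "shuffle"
        shuffle_dir.mkdir(exist_ok=True)
        inputs = shuffling.VariableInputs(
            mirna_profile=mirna_profile, mrna_profile=mrna_profile,
            bs_utr=bs_utr, bs_cds=bs_cds, dbs_utr=dbs_utr, dbs_cds=dbs_cds,
            lengths=lengths,
        )
        k = min(config.top_k, int((mirna_profile > 0).sum()))
        for var in config.shuffle_variables:
            for kind in ("within_top", "random_identity"):
                scheme = shuffling.ShuffleScheme(kind=kind, k=k)
                res = shuffling.simulate_auc_distribution(
                    var, inputs, calls, scheme, n_sim=config.n_sim,
                    seed=config.seed, strict=config.strict_exceedance,
                )
                path = shuffle_dir / f"{var}_{kind}.json"
                res.to_json(path)
                outputs.append(path)
        logger.info("stage shuffle done in %.1fs", time.time() - t)

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "config": asdict(config),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                                      default=str) + "\n")
        logger.info("run complete in %.1fs", time.time() - t0)
        return out
    except (ValidationError, StageError):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        logger.exception("stage %s failed", stage)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def _check_roles(expression: "expr.ExpressionMatrix") -> None:
    roles = {s.role for s in expression.samples}
    for needed in (expr.ROLE_IP, expr.ROLE_FT):
        if needed not in roles:
            raise ValidationError(f"expression matrix has no {needed} samples")


def _sites_from_sequences(config: RunConfig):
    """Build BS/dBS matrices from FASTA inputs (real-data mode)."""
    for name in ("utr_fasta", "cds_fasta", "seeds_file"):
        if getattr(config, name) is None:
            raise ValidationError(f"real-data mode needs {name}")
    records = sequences.read_region_fasta(config.utr_fasta, sequences.REGION_UTR3)
    records += sequences.read_region_fasta(config.cds_fasta, sequences.REGION_CDS)
    seqs = sequences.select_sequences(records)
    seeds = sequences.read_seeds(config.seeds_file)
    genes = seqs.genes_both_regions()
    bs_utr = sequences.build_bs_matrix(seqs, seeds, sequences.REGION_UTR3, genes=genes)
    bs_cds = sequences.build_bs_matrix(seqs, seeds, sequences.REGION_CDS, genes=genes)
    l1 = seqs.lengths(sequences.REGION_UTR3).reindex(genes)
    l2 = seqs.lengths(sequences.REGION_CDS).reindex(genes)
    dbs_utr = sequences.density_matrix(bs_utr, l1)
    dbs_cds = sequences.density_matrix(bs_cds, l2)
    lengths = pd.DataFrame({"L1": l1, "L2": l2})
    lengths.index.name = "gene_id"
    return bs_utr, bs_cds, dbs_utr, dbs_cds, lengths
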