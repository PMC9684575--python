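"""End-to-end orchestration: filters → reversion scan → zygosity → HRD →
signatures → cohort stats, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, io
from .cohort import oncoprint_table
from .copynumber import classify_zygosity
from .filters import FilterConfig, filter_somatic_calls
from .hrd import hrd_sum
from .reversion import call_reversions
from .signatures import SignatureMatrix, build_catalog, fit_signature_weights

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    reference: str
    transcripts: str
    germline: str
    somatic: str
    pairs: str
    segments: str
    outdir: str
    build: Optional[str] = None
    cohort: Optional[str] = None
    signatures_tsv: Optional[str] = None
    seed: int = 0
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    window_aa: int = 200

    def validate(self) -> None:
        for name in ("reference", "transcripts", "germline", "somatic", "pairs", "segments"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise PipelineError("config", f"input path for '{name}' does not exist: {path}")


def _config_hash(cfg: RunConfig) -> str:
    payload = {k: v for k, v in asdict(cfg).items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False)
    tmp.rename(path)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and write the output bundle.

    Outputs: reversion calls TSV, zygosity TSV, HRD TSV (when a genome build
    is given), signature TSV (when a signature matrix is given), cohort
    summary TSV and a JSON run manifest. Re-running with identical inputs is
    byte-identical for the deterministic stages.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        bundles, contigs, transcripts = io.load_patient_bundles(
            cfg.reference, cfg.transcripts, cfg.germline, cfg.somatic,
            cfg.pairs, cfg.segments,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", str(exc)) from exc

    # stage: somatic filters + reversion scan
    try:
        calls = []
        audits = []
        for bundle in bundles:
            retained, audit = filter_somatic_calls(bundle.somatic_variants, cfg.filter_config)
            audits += [(bundle.patient_id, *row) for row in audit]
            bundle.somatic_variants = retained
            calls += call_reversions(bundle, window_aa=cfg.window_aa)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("scan", str(exc)) from exc
    calls_df = pd.DataFrame([{
        "patient_id": c.patient_id, "gene": c.gene,
        "germline_notation": c.germline_notation,
        "somatic_notation": c.somatic_notation,
        "mechanism": c.mechanism, "phasing_method": c.phasing.method,
        "n_cis_pairs": c.phasing.n_cis_pairs, "distance_aa": c.distance_aa,
    } for c in calls], columns=[
        "patient_id", "gene", "germline_notation", "somatic_notation",
        "mechanism", "phasing_method", "n_cis_pairs", "distance_aa",
    ])
    written["calls"] = outdir / "reversion_calls.tsv"
    _atomic_write(calls_df, written["calls"])
    written["filter_audit"] = outdir / "filter_audit.tsv"
    _atomic_write(
        pd.DataFrame(audits, columns=["patient_id", "variant_id", "status", "reason"]),
        written["filter_audit"],
    )

    # stage: zygosity of germline variants
    try:
        zyg_rows = []
        for bundle in bundles:
            if bundle.profile is None:
                continue
            for v in bundle.germline_variants:
                z = classify_zygosity(v, bundle.profile)
                zyg_rows.append({
                    "patient_id": bundle.patient_id, "variant_id": v.variant_id,
                    "zygosity": z.zygosity,
                    "best_m": "" if z.best_m is None else z.best_m,
                })
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("zygosity", str(exc)) from exc
    written["zygosity"] = outdir / "zygosity.tsv"
    _atomic_write(
        pd.DataFrame(zyg_rows, columns=["patient_id", "variant_id", "zygosity", "best_m"]),
        written["zygosity"],
    )

    # stage: HRD scores (needs a genome build)
    if cfg.build:
        try:
            build = io.read_build(cfg.build)
            profiles = io.read_segments(cfg.segments)
            hrd_rows = []
            for pid, profile in sorted(profiles.items()):
                scores = hrd_sum(profile, build)
                hrd_rows.append({
                    "patient_id": pid, "lst": scores.lst, "hrd_loh": scores.hrd_loh,
                    "ntai": scores.ntai, "hrd_sum": scores.hrd_sum,
                    "purity": profile.purity,
                })
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("hrd", str(exc)) from exc
        written["hrd"] = outdir / "hrd_scores.tsv"
        _atomic_write(pd.DataFrame(hrd_rows), written["hrd"])

    # stage: mutational signatures (needs a signature matrix)
    if cfg.signatures_tsv:
        try:
            sigs = SignatureMatrix.from_frame(
                pd.read_csv(cfg.signatures_tsv, sep="\t", index_col=0)
            )
            sig_rows = []
            for bundle in bundles:
                snvs = [
                    v for v in bundle.somatic_variants
                    if len(v.ref) == 1 and len(v.alt) == 1
                ]
                if not snvs:
                    continue
                fit = fit_signature_weights(build_catalog(snvs, contigs), sigs)
                row = {"patient_id": bundle.patient_id, "n_mutations": fit.n_mutations}
                row.update({name: w for name, w in zip(fit.names, fit.weights)})
                sig_rows.append(row)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("signatures", str(exc)) from exc
        written["signatures"] = outdir / "signature_fits.tsv"
        _atomic_write(pd.DataFrame(sig_rows), written["signatures"])

    # stage: cohort summary
    if cfg.cohort:
        try:
            records = io.read_cohort(cfg.cohort)
            loss_of_wt = {
                row["patient_id"]: row["zygosity"] == "biallelic_loss_of_wt"
                for row in zyg_rows
            }
            onco = oncoprint_table(records, calls, loss_of_wt=loss_of_wt)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cohort", str(exc)) from exc
        written["oncoprint"] = outdir / "oncoprint.tsv"
        _atomic_write(onco, written["oncoprint"])

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_patients": len(bundles),
        "n_reversion_calls": int(len(calls_df)),
        "outputs": {k: str(v) for k, v in written.items()},
    }
    manifest_path = outdir / "manifest.json"
    io.write_json(manifest, manifest_path)
    written["manifest"] = manifest_path
    return written
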