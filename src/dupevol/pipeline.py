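"""End-to-end pipeline: configuration, stage orchestration, file I/O.

One :func:`run_pipeline` call executes families -> rates -> triplets ->
asymmetry -> trends on a multi-FASTA of in-frame coding sequences, writes
per-stage TSVs plus a machine-readable JSON report, and logs the gene/pair
counts at every filter.  Identical configuration (including the seedless
deterministic stages) yields byte-identical outputs.

Also houses the packaged fixture of the 26 published asymmetric
substitution-count pairs and the counts-only screen that re-tests them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import asymmetry as asym
from . import families as fam
from . import trends
from . import triplets as trip
from .rates import CodonSequence, RateMatrix, import_rates, rate_matrix

logger = logging.getLogger(__name__)

_FIXTURE_SHA256 = "cec0d1c57459bc4ab80b1c71c355cd066601c980d6217c61f62012a4a7294034"
#: Total pairs tested in the published screen; only the significant 26 are
#: printed, so the meta-test over the fixture uses this stated denominator.
PUBLISHED_N_PAIRS = 144


@dataclass(frozen=True)
class RunConfig:
    """Resolved thresholds and paths for one pipeline run.

    Defaults are the published analysis settings: 75%/20% link thresholds,
    25–98% family identity window, 80% divergence cut, families of >= 3,
    sister window 0.01 <= dS <= 3, individual-rate window
    0.005 <= dS_I <= 0.6, per-pair alpha and meta-test p both 0.05, and the
    100-substitution floor for the trend control.
    """

    input_fasta: str | None = None
    out_dir: str = "dupevol_out"
    min_link_identity: float = 0.75
    min_link_coverage: float = 0.20
    family_min_identity: float = 0.25
    family_max_identity: float = 0.98
    max_divergence: float = 0.80
    family_min_size: int = 3
    sister_ds_min: float = 0.01
    sister_ds_max: float = 3.0
    window_lo: float = 0.005
    window_hi: float = 0.6
    alpha: float = 0.05
    meta_p: float = 0.05
    min_subs: int = 100
    channel: str = "aa"
    sided: str = "two"
    trend_use_floor: bool = False
    rates_table: str | None = None
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in [
            ("min_link_identity", 0, 1), ("min_link_coverage", 0, 1),
            ("family_min_identity", 0, 1), ("family_max_identity", 0, 1),
            ("max_divergence", 0, 1), ("alpha", 0, 1), ("meta_p", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.sister_ds_min > self.sister_ds_max:
            raise ValueError("sister dS window is empty")
        if self.window_lo > self.window_hi:
            raise ValueError("individual-rate window is empty")


# --- FASTA / TSV I/O -------------------------------------------------------

def read_coding_fasta(path: str | Path) -> list[CodonSequence]:
    """Load in-frame coding sequences from multi-FASTA (validated)."""
    return [CodonSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(alignment: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in alignment.items()]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


# --- fixture ---------------------------------------------------------------

def load_fixture_table1() -> list[tuple[str, str, int, int]]:
    """The 26 published asymmetric pairs as (fast_id, slow_id, x_fast,
    x_slow); integrity-checked against a frozen checksum."""
    data = (importlib.resources.files("dupevol") / "data" / "asymmetric_pairs.tsv"
            ).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(f"fixture checksum mismatch: {digest}")
    rows = []
    for line in data.decode().splitlines()[1:]:
        fast_id, fast, slow_id, slow, _fn = line.split("\t")
        rows.append((fast_id, slow_id, int(fast), int(slow)))
    if len(rows) != 26:
        raise ValueError(f"expected 26 fixture rows, found {len(rows)}")
    return rows


def counts_only_screen(alpha: float = 0.05, sided: str = "two",
                       n_pairs: int = PUBLISHED_N_PAIRS,
                       meta_p: float = 0.05) -> dict:
    """Re-test the published substitution counts.

    Applies the exact symmetric binomial test to each of the 26 printed
    pairs and the meta-test over the stated ``n_pairs`` tested pairs.
    """
    rows = []
    for fast_id, slow_id, x_fast, x_slow in load_fixture_table1():
        p = asym.binom_symmetry_test(x_fast, x_slow, sided)
        rows.append({"fast_id": fast_id, "slow_id": slow_id,
                     "x_fast": x_fast, "x_slow": x_slow,
                     "p_value": p, "significant": p < alpha})
    n_sig = sum(r["significant"] for r in rows)
    return {
        "pairs": rows,
        "n_significant": n_sig,
        "n_pairs": n_pairs,
        "asymmetric_fraction": n_sig / n_pairs,
        "meta_p_value": asym.meta_test(n_sig, n_pairs, meta_p),
    }


# --- the pipeline ----------------------------------------------------------

def run_pipeline(config: RunConfig,
                 sequences: Sequence[CodonSequence] | None = None) -> dict:
    """Execute all stages and write per-stage outputs under ``out_dir``.

    Returns the run report (also written as report.json).  An empty input
    produces an empty report without error; a stage failure raises with
    the stage named, leaving earlier outputs on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    t_start = time.perf_counter()

    if sequences is None:
        if config.input_fasta is None:
            raise ValueError("run_pipeline needs sequences or input_fasta")
        sequences = read_coding_fasta(config.input_fasta)
    logger.info("input: %d coding sequences", len(sequences))
    report["stages"]["input"] = {"genes_in": len(sequences)}

    stage = "families"
    try:
        families, rejects = fam.build_families(
            sequences, config.min_link_identity, config.min_link_coverage,
            config.family_min_identity, config.family_max_identity,
            config.max_divergence, config.family_min_size)
        for f in families:
            write_fasta(f.alignment, out / f"{f.family_id}.aln.fasta")
        fam_rows = [{"family": f.family_id, "members": ",".join(f.members),
                     **f.qc} for f in families]
        write_tsv(pd.DataFrame(fam_rows), out / "families.tsv")
        n_in_families = sum(len(f.members) for f in families)
        logger.info("families: %d kept (%d genes), %d groups rejected",
                    len(families), n_in_families, len(rejects))
        report["stages"]["families"] = {
            "families_kept": len(families), "genes_kept": n_in_families,
            "groups_rejected": len(rejects),
            "rejections": rejects,
        }

        stage = "rates"
        matrices: list[RateMatrix] = []
        if config.rates_table is not None:
            for f in families:
                matrices.append(import_rates(config.rates_table,
                                             list(f.members), f.family_id))
        else:
            for f in families:
                matrices.append(rate_matrix(f.alignment, f.family_id))
        if matrices:
            write_tsv(pd.concat([m.to_frame() for m in matrices]),
                      out / "rates.tsv")
        n_sat = sum(pr.saturated for m in matrices for pr in m.iter_pairs())
        report["stages"]["rates"] = {
            "pairs": sum(1 for m in matrices for _ in m.iter_pairs()),
            "saturated_pairs": n_sat,
        }

        stage = "triplets"
        all_triplets = []
        for m in matrices:
            all_triplets.extend(trip.build_triplets(
                m, config.sister_ds_min, config.sister_ds_max))
        windowed, n_window_dropped = trip.rate_window_filter(
            all_triplets, config.window_lo, config.window_hi)
        write_tsv(trip.triplets_frame(all_triplets), out / "triplets.tsv")
        logger.info("triplets: %d computed, %d in dS_I window",
                    len(all_triplets), len(windowed))
        report["stages"]["triplets"] = {
            "triplets_computed": len(all_triplets),
            "dropped_by_window": n_window_dropped,
            "triplets_kept": len(windowed),
        }

        stage = "asymmetry"
        alignments = {f.family_id: f.alignment for f in families}
        results, meta = asym.run_asymmetry_screen(
            matrices, alignments, alpha=config.alpha, channel=config.channel,
            sided=config.sided, p_asym=config.meta_p)
        write_tsv(asym.results_frame(results), out / "asymmetry.tsv")
        logger.info("asymmetry: %d/%d pairs significant, meta p=%.3g",
                    meta.n_asymmetric, meta.n_pairs, meta.p_value)
        report["stages"]["asymmetry"] = {
            "pairs_tested": meta.n_pairs,
            "pairs_significant": meta.n_asymmetric,
            "meta_p_value": meta.p_value,
        }

        stage = "trends"
        trend_triplets = windowed
        if config.trend_use_floor:
            trend_triplets, n_floor = trends.substitution_floor_filter(
                windowed, alignments, config.min_subs)
            report["stages"].setdefault("trends", {})["dropped_by_floor"] = n_floor
        points = [(t.dS_I, t.omega_I) for t in trend_triplets
                  if t.dS_I > 0]
        trend_report: dict = dict(report["stages"].get("trends", {}))
        if len(points) >= 3:
            fit = trends.fit_trend(points, subset_label="all")
            trend_report.update({
                "n_points": fit.n, "slope": fit.slope,
                "ci95": [fit.ci95_lo, fit.ci95_hi],
                "degenerate": fit.degenerate,
            })
        else:
            trend_report.update({"n_points": len(points), "slope": None})
        summaries = trends.family_summaries(matrices)
        write_tsv(trends.summaries_frame(summaries), out / "family_summaries.tsv")
        report["stages"]["trends"] = trend_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["runtime_s"] = round(time.perf_counter() - t_start, 3)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
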