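"""Per-replicon orchestration and size-stratified cohort classification.

Each replicon is pushed through every stage — KOPS detection and
circular statistics, word exceptionality of the KOPS motif, matS scan
with Markov-recoded Poisson enrichment, xrs/AS detection — and assigned
one of four dimer-resolution categories:

* ``FtsK_chromosome_like`` — carries at least one 28 bp xrs devoid of
  accessory sequence (the chromosome-like, FtsK-dependent class);
* ``AS_plasmid`` — carries an xrs flanked by an ArgR/ArcA accessory
  region (FtsK-independent resolution, typical of small plasmids);
* ``self_encoded_only`` — no usable xrs but a self-encoded
  site-specific recombinase (an input flag: recombinase detection by
  HMM profile search is deliberately outside this package);
* ``unresolved`` — none of the above.

Category assignment is a pure function of the stage outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mats_pssm as mp
from .kops_circular import (
    ConvergenceCall,
    circular_summary,
    convergence_call,
    find_kops,
    project_angles,
)
from .sequence_io import FeatureRecord, Replicon, read_fasta, write_bed
from .synthetic_data import _get_toolkit
from .word_exceptionality import exceptionality_score
from .xrs_as_detector import classify_xrs, detect_as, scan_xrs

KOPS_PATTERN_FWD = "GGGNAGGG"
KOPS_PATTERN_REV = "CCCTNCCC"

#: size-bin edges for the cohort summary, kb landmarks of the survey
SIZE_BIN_EDGES_KB = (25, 100, 200, 250, 500)


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    n_null: int = 1000
    pseudocount: float = 0.5
    seed: int = 0
    as_window: int = 200
    as_band: tuple[int, int] = (10, 200)


@dataclass
class RepliconReport:
    id: str
    length: int
    has_recombinase: bool
    xrs: list  # (XrsCandidate, AccessoryRegion | None, XrsClassification)
    convergence: ConvergenceCall | None
    word_forward: object | None
    word_reverse: object | None
    mats_hits: list
    enrichment: mp.MatsEnrichment | None
    category: str


def _categorize(report_xrs, has_recombinase: bool) -> str:
    cats = [cls.category for _, _, cls in report_xrs]
    if "AS_free_28bp" in cats:
        return "FtsK_chromosome_like"
    if "AS_associated" in cats:
        return "AS_plasmid"
    if has_recombinase:
        return "self_encoded_only"
    return "unresolved"


def run_replicon(
    replicon: Replicon,
    has_recombinase: bool = False,
    config: PipelineConfig | None = None,
    toolkit=None,
) -> RepliconReport:
    """All stages for one replicon, assembled into a report.

    Stage failures are re-raised with the replicon id for context.
    The enrichment null stream is seeded from ``config.seed``.
    """
    config = config or PipelineConfig()
    tk = toolkit or _get_toolkit()
    try:
        candidates = scan_xrs(replicon, tk.pwms, tk.params)
        xrs_results = []
        for cand in candidates:
            acc = detect_as(
                replicon,
                cand,
                tk.as_pwms["ArgR"],
                tk.as_pwms["ArcA"],
                window=config.as_window,
                band=config.as_band,
            )
            xrs_results.append((cand, acc, classify_xrs(cand, acc)))

        fwd, rev = find_kops(replicon)
        convergence = None
        if candidates:
            best = max(candidates, key=lambda c: c.combined_score)
            center = (best.position + best.total_len // 2) % replicon.length
            f_stat = (
                circular_summary(project_angles(fwd, replicon.length, center))
                if fwd
                else None
            )
            r_stat = (
                circular_summary(project_angles(rev, replicon.length, center))
                if rev
                else None
            )
            convergence = convergence_call(f_stat, r_stat, alpha=config.alpha)

        def _word(pattern):
            try:
                return exceptionality_score(replicon.seq, pattern)
            except ValueError:
                return None  # sequence too short for the maximal model

        word_f = _word(KOPS_PATTERN_FWD)
        word_r = _word(KOPS_PATTERN_REV)

        mats_hits = mp.scan_mats(tk.pssm, replicon)
        enrichment = mp.mats_enrichment(
            replicon, tk.pssm, n_null=config.n_null, seed=config.seed
        )
        return RepliconReport(
            id=replicon.id,
            length=replicon.length,
            has_recombinase=has_recombinase,
            xrs=xrs_results,
            convergence=convergence,
            word_forward=word_f,
            word_reverse=word_r,
            mats_hits=mats_hits,
            enrichment=enrichment,
            category=_categorize(xrs_results, has_recombinase),
        )
    except Exception as exc:
        raise RuntimeError(f"replicon {replicon.id!r}: {exc}") from exc


def report_row(rep: RepliconReport) -> dict:
    conv = rep.convergence
    enr = rep.enrichment
    return {
        "id": rep.id,
        "length": rep.length,
        "has_recombinase": rep.has_recombinase,
        "n_xrs": len(rep.xrs),
        "xrs_categories": ";".join(sorted(c.category for _, _, c in rep.xrs)) or "none",
        "best_xrs_pos": (
            max(rep.xrs, key=lambda t: t[0].combined_score)[0].position
            if rep.xrs
            else -1
        ),
        "kops_forward_n": conv.forward_stat.n if conv and conv.forward_stat else 0,
        "kops_reverse_n": conv.reverse_stat.n if conv and conv.reverse_stat else 0,
        "convergence": conv.verdict if conv else "no_xrs",
        "word_fwd_score": rep.word_forward.score if rep.word_forward else np.nan,
        "word_fwd_verdict": rep.word_forward.verdict if rep.word_forward else "undefined",
        "word_rev_score": rep.word_reverse.score if rep.word_reverse else np.nan,
        "word_rev_verdict": rep.word_reverse.verdict if rep.word_reverse else "undefined",
        "mats_k": enr.k if enr else 0,
        "mats_lambda": enr.lam if enr else np.nan,
        "mats_p_point": enr.p_point if enr else np.nan,
        "mats_p_tail": enr.p_tail if enr else np.nan,
        "category": rep.category,
    }


def run_cohort(
    replicons: list[Replicon] | str | Path,
    flags: dict[str, bool] | str | Path | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
):
    """Classify a cohort; returns (per-replicon table, size-bin summary).

    ``flags`` maps replicon id to recombinase presence (TSV with columns
    id, has_recombinase also accepted); ids present in only one of FASTA
    and flag table are an error.  Rows are sorted by replicon length;
    the run is deterministic for a fixed config seed.
    """
    config = config or PipelineConfig()
    if isinstance(replicons, (str, Path)):
        replicons = read_fasta(replicons)
    if not replicons:
        raise ValueError("empty cohort")
    if isinstance(flags, (str, Path)):
        fdf = pd.read_csv(flags, sep="\t")
        flags = dict(zip(fdf["id"].astype(str), fdf["has_recombinase"].astype(bool)))
    flags = flags or {}
    if flags:
        fasta_ids = {r.id for r in replicons}
        orphans = sorted(fasta_ids ^ set(flags))
        if orphans:
            raise ValueError(f"flag table / FASTA id mismatch: {orphans}")

    tk = _get_toolkit()
    ordered = sorted(replicons, key=lambda r: (r.length, r.id))
    rows, features = [], []
    for i, rep in enumerate(ordered):
        cfg_i = PipelineConfig(
            alpha=config.alpha,
            n_null=config.n_null,
            pseudocount=config.pseudocount,
            seed=config.seed + 1009 * i,
            as_window=config.as_window,
            as_band=config.as_band,
        )
        report = run_replicon(
            rep, has_recombinase=flags.get(rep.id, False), config=cfg_i, toolkit=tk
        )
        rows.append(report_row(report))
        fwd, rev = find_kops(rep)
        features += [
            FeatureRecord(rep.id, p, p + 8, "+", "KOPS", wraps=p + 8 > rep.length)
            for p in fwd
        ]
        features += [
            FeatureRecord(rep.id, p, p + 8, "-", "KOPS", wraps=p + 8 > rep.length)
            for p in rev
        ]
        features += [
            FeatureRecord(
                rep.id, h.position, h.position + 13, h.strand, "matS", h.score,
                wraps=h.position + 13 > rep.length,
            )
            for h in report.mats_hits
        ]
        features += [
            FeatureRecord(
                rep.id, c.position, c.position + c.total_len, c.strand, "xrs",
                c.combined_score, wraps=c.position + c.total_len > rep.length,
            )
            for c, _, _ in report.xrs
        ]

    table = pd.DataFrame(rows)
    edges = [0] + [kb * 1000 for kb in SIZE_BIN_EDGES_KB] + [np.inf]
    labels = (
        [f"<{SIZE_BIN_EDGES_KB[0]}kb"]
        + [
            f"{a}-{b}kb"
            for a, b in zip(SIZE_BIN_EDGES_KB[:-1], SIZE_BIN_EDGES_KB[1:])
        ]
        + [f">{SIZE_BIN_EDGES_KB[-1]}kb"]
    )
    table["size_bin"] = pd.cut(
        table["length"], bins=edges, labels=labels, right=False
    )
    summary = (
        table.groupby("size_bin", observed=False)["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reset_index()
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        write_bed(features, out_dir / "features.bed")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(
                {
                    "n_replicons": len(table),
                    "categories": table["category"].value_counts().to_dict(),
                    "seed": config.seed,
                },
                fh,
                indent=2,
            )
    return table, summary
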