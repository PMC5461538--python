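"""Multi-engine PSM aggregation by FDR score and combined FDR score.

Raw search-engine scores (XCorr for COMET/Crux-like engines, e-value for
MS-GF+-like engines) are not comparable across engines. Target-decoy FDR
estimates along each engine's ranked PSM list are, so each PSM first
receives an engine FDR score: per-rank decoy/target ratios are turned into
q-values (monotone from the worst score upward) that anchor the decoy
positions, and targets between anchors are linearly interpolated in rank.

PSMs found by two or more engines are then pooled per engine-agreement
partition: the arithmetic mean of the engine FDR scores re-ranks the
partition and the same anchored-q-value estimator is re-applied to its own
target/decoy labels, yielding the combined FDR score. This corrects for
engine-agreement subsets that contain few or no decoys.

The multistage filter retains reference-search PSMs with an individual
FDR score <= 0.01 or a combined FDR score <= 0.01, provided at least one
engine gave <= 0.05; for novel (proteogenomic) PSMs, identification by at
least two engines is additionally required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

ENGINES = ("cometlike", "cruxlike", "msgflike")
ENGINE_DIRECTION = {
    "cometlike": "higher_better",  # XCorr
    "cruxlike": "higher_better",  # XCorr
    "msgflike": "lower_better",  # e-value
}

PsmKey = tuple[str, str, tuple]  # (spectrum_id, peptide, mods)


@dataclass(frozen=True)
class PsmRecord:
    """One engine's best peptide-to-spectrum match for one spectrum."""

    spectrum_id: str
    peptide: str
    mods: tuple  # ((position, name, delta_da), ...), position 0 = N terminus
    engine: str
    raw_score: float
    score_direction: str
    is_decoy: bool

    @property
    def key(self) -> PsmKey:
        return (self.spectrum_id, self.peptide, self.mods)


@dataclass
class FdrScoredPsm:
    key: PsmKey
    is_decoy: bool
    engine_fdr_scores: dict[str, float] = field(default_factory=dict)
    combined_fdr_score: float | None = None
    small_partition: bool = False
    passes_stage1: bool = False
    passes_novel: bool = False

    @property
    def engine_set(self) -> frozenset[str]:
        return frozenset(self.engine_fdr_scores)

    @property
    def combined_raw(self) -> float | None:
        if len(self.engine_fdr_scores) < 2:
            return None
        vals = self.engine_fdr_scores.values()
        return sum(vals) / len(vals)


def _anchored_fdr_scores(ordered_decoy_flags: Sequence[bool]) -> list[float]:
    """FDR scores for PSMs already ranked best-first (decoys after targets on ties).

    Per-rank FDP = #decoys/max(1, #targets) capped at 1; q-values by running
    minimum from the worst rank; decoy ranks are the anchors and targets are
    interpolated linearly in rank between surrounding anchors (0 before the
    first anchor, the last anchor's value after it).
    """
    n = len(ordered_decoy_flags)
    if n == 0:
        return []
    fdp = []
    t = d = 0
    for flag in ordered_decoy_flags:
        if flag:
            d += 1
        else:
            t += 1
        fdp.append(min(1.0, d / max(1, t)))
    q = fdp[:]
    for i in range(n - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    anchors = [(i, q[i]) for i, flag in enumerate(ordered_decoy_flags) if flag]
    scores = [0.0] * n
    if not anchors:
        return scores
    a_idx = 0
    for i, flag in enumerate(ordered_decoy_flags):
        if flag:
            scores[i] = q[i]
            a_idx += 1
            continue
        if a_idx == 0:
            scores[i] = 0.0
        elif a_idx == len(anchors):
            scores[i] = anchors[-1][1]
        else:
            (ra, qa), (rb, qb) = anchors[a_idx - 1], anchors[a_idx]
            scores[i] = qa + (qb - qa) * (i - ra) / (rb - ra)
    return scores


def engine_fdr_scores(psms: Sequence[PsmRecord]) -> dict[PsmKey, float]:
    """Per-engine FDR score for each PSM of one engine's result list.

    Input must hold one best PSM per spectrum. PSMs are ranked direction-aware
    (higher XCorr / lower e-value first) with decoys after targets on raw-score
    ties (conservative).
    """
    if not psms:
        return {}
    engines = {p.engine for p in psms}
    if len(engines) > 1:
        raise ValueError(f"mixed engines in one scoring pass: {engines}")
    direction = psms[0].score_direction

    def quality(p: PsmRecord) -> float:
        return -p.raw_score if direction == "higher_better" else p.raw_score

    ordered = sorted(psms, key=lambda p: (quality(p), p.is_decoy))
    scores = _anchored_fdr_scores([p.is_decoy for p in ordered])
    return {p.key: s for p, s in zip(ordered, scores)}


def combined_fdr(
    scored_by_engine: dict[str, dict[PsmKey, float]],
    decoy_flags: dict[PsmKey, bool],
    small_partition_floor: int = 10,
) -> list[FdrScoredPsm]:
    """Merge per-engine FDR-score maps into combined-FDR-scored PSMs.

    ``decoy_flags`` carries each key's target/decoy label (identical across
    engines by construction of the concatenated database; disagreement means
    library corruption and raises). Within each engine-agreement partition of
    >= 2 engines, keys are re-ranked by the mean of their engine FDR scores
    and the anchored q-value estimator is re-applied. Partitions smaller than
    ``small_partition_floor`` are flagged.
    """
    merged: dict[PsmKey, FdrScoredPsm] = {}
    for engine, table in scored_by_engine.items():
        for key, score in table.items():
            if key not in decoy_flags:
                raise ValueError(f"no decoy flag for key {key}")
            rec = merged.get(key)
            if rec is None:
                rec = FdrScoredPsm(key=key, is_decoy=decoy_flags[key])
                merged[key] = rec
            elif rec.is_decoy != decoy_flags[key]:
                raise ValueError(f"inconsistent decoy flag across engines for {key}")
            rec.engine_fdr_scores[engine] = score

    partitions: dict[frozenset[str], list[FdrScoredPsm]] = {}
    for rec in merged.values():
        if len(rec.engine_fdr_scores) >= 2:
            partitions.setdefault(rec.engine_set, []).append(rec)
    for members in partitions.values():
        members.sort(key=lambda r: (r.combined_raw, r.is_decoy))
        scores = _anchored_fdr_scores([r.is_decoy for r in members])
        small = len(members) < small_partition_floor
        for rec, s in zip(members, scores):
            rec.combined_fdr_score = s
            rec.small_partition = small
    return list(merged.values())


def multistage_filter(
    psms: Iterable[FdrScoredPsm],
    stage: Literal["reference", "novel"],
    individual_threshold: float = 0.01,
    combined_threshold: float = 0.01,
    safeguard_threshold: float = 0.05,
) -> list[FdrScoredPsm]:
    """Apply the staged confidence filters, annotating pass flags.

    reference: (min engine FDR score <= 0.01 OR combined FDR score <= 0.01)
    AND min engine FDR score <= 0.05. novel: additionally >= 2 engines.
    """
    retained: list[FdrScoredPsm] = []
    for rec in psms:
        best = min(rec.engine_fdr_scores.values())
        core = best <= individual_threshold or (
            rec.combined_fdr_score is not None
            and rec.combined_fdr_score <= combined_threshold
        )
        keep = core and best <= safeguard_threshold
        rec.passes_stage1 = keep
        rec.passes_novel = keep and len(rec.engine_fdr_scores) >= 2
        if stage == "novel":
            if rec.passes_novel:
                retained.append(rec)
        elif rec.passes_stage1:
            retained.append(rec)
    return retained


def unidentified_spectra(
    all_psms: Iterable[FdrScoredPsm], retained: Iterable[FdrScoredPsm]
) -> set[str]:
    """Spectrum ids with no retained PSM: the input to the novel search."""
    kept = {rec.key[0] for rec in retained}
    return {rec.key[0] for rec in all_psms} - kept


# -- tabular IO ---------------------------------------------------------------

def _mods_to_str(mods: tuple) -> str:
    return ";".join(f"{p}:{name}:{delta:+.2f}" for p, name, delta in mods)


def parse_mods(text: str) -> tuple:
    if not text or text in ("-", "nan"):
        return ()
    out = []
    for item in str(text).split(";"):
        pos, name, delta = item.split(":")
        out.append((int(pos), name, float(delta)))
    return tuple(out)


def read_psm_table(path: str | Path, engine: str) -> list[PsmRecord]:
    """Read one engine's PSM TSV (spectrum_id, peptide, mods, score, decoy).

    The engine name fixes the score direction (cometlike/cruxlike: XCorr,
    higher better; msgflike: e-value, lower better). One best PSM per
    spectrum is kept (direction-aware) — engines' ranks beyond 1 are
    discarded at ingest.
    """
    if engine not in ENGINE_DIRECTION:
        raise ValueError(f"unknown engine dialect {engine!r}")
    direction = ENGINE_DIRECTION[engine]
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str})
    df["mods"] = df["mods"].fillna("")
    best = df.sort_values(
        "score", ascending=(direction == "lower_better"), kind="mergesort"
    ).drop_duplicates("spectrum_id", keep="first")
    return [
        PsmRecord(
            spectrum_id=row.spectrum_id,
            peptide=row.peptide,
            mods=parse_mods(row.mods),
            engine=engine,
            raw_score=float(row.score),
            score_direction=direction,
            is_decoy=bool(row.decoy),
        )
        for row in best.itertuples()
    ]


def write_scored_table(psms: Iterable[FdrScoredPsm], path: str | Path) -> None:
    rows = []
    for rec in psms:
        rows.append(
            {
                "spectrum_id": rec.key[0],
                "peptide": rec.key[1],
                "mods": _mods_to_str(rec.key[2]),
                "decoy": int(rec.is_decoy),
                "engines": ",".join(sorted(rec.engine_fdr_scores)),
                "min_engine_fdr": min(rec.engine_fdr_scores.values()),
                "combined_fdr": (
                    "" if rec.combined_fdr_score is None else rec.combined_fdr_score
                ),
                "small_partition": int(rec.small_partition),
                "passes_stage1": int(rec.passes_stage1),
                "passes_novel": int(rec.passes_novel),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
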