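"""Per-run PSM filtering and closed/open search integration.

The two engines identify overlapping spectrum sets.  After per-run FDR and
site-localization filtering, results are merged per (run, spectrum): when the
engines agree on the peptidoform the spectrum is kept once; when they
conflict, the closed-search assignment wins; spectra seen by only one engine
pass through.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict

from .records import Engine, MergedPsm, Provenance, PsmRecord, parse_peptidoform

logger = logging.getLogger(__name__)


def filter_open_psms(psms: list[PsmRecord], fdr: float) -> list[PsmRecord]:
    """Keep open-search PSMs with q_value <= fdr, independently per run.

    The threshold is inclusive.  The q-values are per-run to begin with, so
    per-run filtering reduces to a row filter; runs never influence each
    other.
    """
    for p in psms:
        if p.engine is not Engine.OPEN:
            raise ValueError(f"{p.spectrum_id}: filter_open_psms expects open-engine PSMs")
    kept = [p for p in psms if p.q_value <= fdr]
    logger.info("open-search FDR filter (q<=%g): kept %d of %d PSMs", fdr, len(kept), len(psms))
    return kept


def filter_closed_psms(psms: list[PsmRecord], fdr: float | None) -> list[PsmRecord]:
    """Optional q-value filter for closed-search PSMs (pre-filtered upstream)."""
    if fdr is None:
        return list(psms)
    kept = [p for p in psms if p.q_value <= fdr]
    logger.info("closed-search FDR filter (q<=%g): kept %d of %d PSMs", fdr, len(kept), len(psms))
    return kept


def _has_ambiguous_site(psm: PsmRecord) -> bool:
    """True if any modification sits on a residue occurring more than once."""
    peptide, mods = parse_peptidoform(psm.peptidoform)
    for pos, _name in mods:
        residue = peptide[pos - 1]
        if peptide.count(residue) > 1:
            return True
    return False


def filter_localization(psms: list[PsmRecord], min_score: float) -> list[PsmRecord]:
    """Drop positionally ambiguous modified PSMs with weak localization.

    A PSM whose modification target residue occurs more than once in the
    peptide is kept only with loc_score strictly above ``min_score``.
    Unmodified PSMs and unambiguous sites pass unconditionally; ambiguous
    PSMs lacking a localization score are dropped with a warning.
    """
    kept: list[PsmRecord] = []
    n_no_score = n_low = 0
    for p in psms:
        if not p.is_modified or not _has_ambiguous_site(p):
            kept.append(p)
        elif p.loc_score is None:
            n_no_score += 1
        elif p.loc_score > min_score:
            kept.append(p)
        else:
            n_low += 1
    if n_no_score:
        logger.warning("localization filter: dropped %d ambiguous PSMs lacking loc_score",
                       n_no_score)
    if n_low:
        logger.info("localization filter (> %g): dropped %d low-confidence PSMs",
                    min_score, n_low)
    return kept


def _key_unique(psms: list[PsmRecord], engine: str) -> dict[tuple[str, str], PsmRecord]:
    by_key: dict[tuple[str, str], PsmRecord] = {}
    for p in psms:
        key = (p.run_id, p.spectrum_id)
        if key in by_key:
            raise ValueError(
                f"duplicate (run_id, spectrum_id) {key} within {engine} results; "
                "upstream must provide the best PSM per spectrum"
            )
        by_key[key] = p
    return by_key


def merge_searches(closed: list[PsmRecord], open_: list[PsmRecord]) -> list[MergedPsm]:
    """Merge filtered closed- and open-search PSMs per (run, spectrum).

    Identical peptidoform → both_agree (closed record carried); differing
    peptidoform → closed record kept, provenance conflict_closed_kept;
    single-engine spectra pass through.  Output order: closed records in
    input order, then open-only records in input order.
    """
    closed_by_key = _key_unique(closed, "closed")
    open_by_key = _key_unique(open_, "open")

    merged: list[MergedPsm] = []
    for p in closed:
        other = open_by_key.get((p.run_id, p.spectrum_id))
        if other is None:
            prov = Provenance.CLOSED_ONLY
        elif other.peptidoform == p.peptidoform:
            prov = Provenance.BOTH_AGREE
        else:
            prov = Provenance.CONFLICT_CLOSED_KEPT
        merged.append(MergedPsm(psm=p, provenance=prov))
    for p in open_:
        if (p.run_id, p.spectrum_id) not in closed_by_key:
            merged.append(MergedPsm(psm=p, provenance=Provenance.OPEN_ONLY))
    return merged


def summarize_id_rate(merged: list[MergedPsm],
                      spectra_per_run: dict[str, int]) -> tuple[dict[str, float], float]:
    """Per-run identified-spectra fractions and their median."""
    counts: dict[str, int] = defaultdict(int)
    for m in merged:
        if m.run_id not in spectra_per_run:
            raise ValueError(f"run {m.run_id!r} missing from spectra_per_run")
        counts[m.run_id] += 1
    rates: dict[str, float] = {}
    for run_id, total in spectra_per_run.items():
        if total <= 0:
            raise ValueError(f"run {run_id!r} reports zero acquired spectra")
        rates[run_id] = counts.get(run_id, 0) / total
    return rates, statistics.median(rates.values())
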