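"""Physicochemical characterization: molecular weight, isoelectric point,
and observed-vs-unobserved summaries of the pan-proteome.

Masses come from the shipped residue-mass table (``data/aa_masses.tsv``):
monoisotopic masses for peptide-level work, average masses for conventional
protein molecular weight.  The isoelectric point is the pH at which the
Henderson–Hasselbalch net charge over the termini and the D, E, C, Y, H, K,
R side chains (pKa values from ``data/pka.tsv``, EMBOSS set) is zero; net
charge is strictly decreasing in pH, so the root is found by bisection on
[0, 14].
"""

from __future__ import annotations

import statistics
from importlib import resources

import pandas as pd

from .config import PipelineConfig
from .database import PanDatabase, count_detectable_peptides
from .records import Tier, TierAssignment

PI_TOLERANCE = 1e-4


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("panatlas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


_masses = _load_table("aa_masses.tsv")
MONOISOTOPIC_MASS: dict[str, float] = dict(zip(_masses.residue, _masses.monoisotopic))
AVERAGE_MASS: dict[str, float] = dict(zip(_masses.residue, _masses.average))
WATER_MONO = 18.0105646863
WATER_AVG = 18.01528

_pka = _load_table("pka.tsv")
PKA: dict[str, float] = dict(zip(_pka.group, _pka.pka))
_SIGN: dict[str, int] = dict(zip(_pka.group, _pka.sign.astype(int)))
_SIDE_CHAINS = [g for g in PKA if g not in ("nterm", "cterm")]


def molecular_weight(sequence: str, kind: str = "average",
                     permissive: bool = False) -> float:
    """Protein/peptide mass: residue masses plus one water.

    ``kind`` is "average" or "monoisotopic".  Sequences containing X have no
    defined mass and raise, unless ``permissive`` is set, in which case X
    positions are skipped (partial mass, flagged to the caller by choice of
    flag, not in the return value).
    """
    if not sequence:
        raise ValueError("empty sequence")
    table, water = (
        (AVERAGE_MASS, WATER_AVG) if kind == "average"
        else (MONOISOTOPIC_MASS, WATER_MONO)
    )
    if kind not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass kind {kind!r}")
    total = water
    for res in sequence:
        if res == "X":
            if permissive:
                continue
            raise ValueError("sequence contains X; no defined mass (use permissive=True)")
        total += table[res]
    return total


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    positive = 1.0 / (1.0 + 10.0 ** (ph - PKA["nterm"]))
    negative = 1.0 / (1.0 + 10.0 ** (PKA["cterm"] - ph))
    for group in _SIDE_CHAINS:
        n = sequence.count(group)
        if not n:
            continue
        if _SIGN[group] > 0:
            positive += n / (1.0 + 10.0 ** (ph - PKA[group]))
        else:
            negative += n / (1.0 + 10.0 ** (PKA[group] - ph))
    return positive - negative


def isoelectric_point(sequence: str) -> float:
    """pH of zero net charge, by bisection on [0, 14] to 1e-4."""
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > PI_TOLERANCE:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def characterize_sets(
    db: PanDatabase,
    tiers: list[TierAssignment],
    config: PipelineConfig,
    localization_labels: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-group physicochemical table plus observed/unobserved medians.

    A group is *observed* at any tier except not_observed.  X-containing
    sequences get masses over their X-free positions (has_x flags them).
    Optional localization labels are joined verbatim.
    """
    tier_by_group = {t.group_id: t.tier for t in tiers if not t.is_decoy}
    rows = []
    for gid, rec in enumerate(db.targets):
        seq = rec.sequence
        tier = tier_by_group.get(gid, Tier.NOT_OBSERVED)
        row = {
            "group_id": gid,
            "accession": rec.accession,
            "length": len(seq),
            "average_mass": molecular_weight(seq, "average", permissive=True),
            "monoisotopic_mass": molecular_weight(seq, "monoisotopic", permissive=True),
            "isoelectric_point": isoelectric_point(seq),
            "n_detectable_peptides": count_detectable_peptides(seq, config),
            "has_x": "X" in seq,
            "tier": tier.value,
            "observed": tier is not Tier.NOT_OBSERVED,
        }
        if localization_labels is not None:
            row["localization"] = localization_labels.get(gid, "")
        rows.append(row)
    table = pd.DataFrame(rows)

    summary: dict[str, dict[str, float]] = {}
    for label, subset in (
        ("observed", table[table.observed]),
        ("unobserved", table[~table.observed]),
    ):
        if len(subset) == 0:
            summary[label] = {}
            continue
        summary[label] = {
            "n": float(len(subset)),
            "median_mass": float(statistics.median(subset.average_mass)),
            "median_pi": float(statistics.median(subset.isoelectric_point)),
            "median_length": float(statistics.median(subset.length)),
            "median_detectable_peptides": float(
                statistics.median(subset.n_detectable_peptides)),
        }
    return table, summary
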