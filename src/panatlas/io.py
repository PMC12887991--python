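"""Readers and writers for every external format the pipeline touches.

FASTA goes through Biopython's SeqIO; PSM tables are plain TSV with a header
row, handled with pandas; trees are serialized as Newick through scikit-bio.
All parsing is total and order-preserving: every input row either yields one
record or raises a diagnosed error naming the offending location.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from skbio.tree import TreeNode

from .records import (
    Engine,
    MergedPsm,
    Provenance,
    ProteoformRecord,
    PsmRecord,
    Source,
)

PSM_REQUIRED_COLUMNS = ("run_id", "spectrum_id", "peptidoform", "charge", "score", "q_value")


def read_fasta(path: str | Path, strain_id: str | None, source: Source) -> list[ProteoformRecord]:
    """Read one proteome FASTA into ProteoformRecords.

    The header token before the first whitespace becomes the accession;
    sequences are uppercased.  ``strain_id`` may be None for phage or
    contaminant collections.
    """
    path = Path(path)
    records: list[ProteoformRecord] = []
    with open(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = str(entry.seq).upper()
            if not seq:
                raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
            strains = frozenset([strain_id]) if strain_id else frozenset()
            records.append(
                ProteoformRecord(
                    accession=entry.id,
                    sequence=seq,
                    source=source,
                    strain_ids=strains,
                )
            )
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: list[ProteoformRecord], path: str | Path,
                include_provenance: bool = True) -> None:
    """Write records as FASTA; provenance is encoded in the description."""
    with open(path, "w") as out:
        for rec in records:
            if include_provenance:
                strains = ";".join(sorted(rec.strain_ids))
                desc = f" source={rec.source.value} strains={strains}"
                if rec.merged_accessions:
                    desc += " merged=" + ";".join(rec.merged_accessions)
            else:
                desc = ""
            out.write(f">{rec.accession}{desc}\n")
            for i in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[i:i + 60] + "\n")


def read_fasta_with_provenance(path: str | Path) -> list[ProteoformRecord]:
    """Read back a FASTA written by :func:`write_fasta` (round-trip)."""
    path = Path(path)
    records: list[ProteoformRecord] = []
    with open(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            fields = dict(
                tok.split("=", 1) for tok in entry.description.split()[1:] if "=" in tok
            )
            source = Source(fields.get("source", "strain"))
            strains = frozenset(s for s in fields.get("strains", "").split(";") if s)
            merged = tuple(m for m in fields.get("merged", "").split(";") if m)
            records.append(
                ProteoformRecord(
                    accession=entry.id,
                    sequence=str(entry.seq).upper(),
                    source=source,
                    strain_ids=strains,
                    is_decoy=entry.id.startswith("DECOY_"),
                    merged_accessions=merged,
                )
            )
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def read_psm_table(path: str | Path, engine: Engine) -> list[PsmRecord]:
    """Read a per-run PSM TSV produced by one search engine.

    Required columns: run_id, spectrum_id, peptidoform, charge, score,
    q_value; loc_score is optional.  The bare peptide is derived by stripping
    bracketed modification annotations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "spectrum_id": str})
    missing = [c for c in PSM_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    has_loc = "loc_score" in df.columns
    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        loc = getattr(row, "loc_score", None) if has_loc else None
        if loc is not None and pd.isna(loc):
            loc = None
        records.append(
            PsmRecord(
                run_id=str(row.run_id),
                spectrum_id=str(row.spectrum_id),
                engine=engine,
                peptidoform=str(row.peptidoform),
                charge=int(row.charge),
                score=float(row.score),
                q_value=float(row.q_value),
                loc_score=None if loc is None else float(loc),
            )
        )
    return records


def write_psm_table(psms: list[PsmRecord], path: str | Path) -> None:
    rows = [
        {
            "run_id": p.run_id,
            "spectrum_id": p.spectrum_id,
            "peptidoform": p.peptidoform,
            "charge": p.charge,
            "score": p.score,
            "q_value": p.q_value,
            "loc_score": "" if p.loc_score is None else p.loc_score,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=["run_id", "spectrum_id", "peptidoform", "charge",
                                "score", "q_value", "loc_score"]).to_csv(
        path, sep="\t", index=False)


def write_merged_table(merged: list[MergedPsm], path: str | Path) -> None:
    rows = [
        {
            "run_id": m.run_id,
            "spectrum_id": m.spectrum_id,
            "engine": m.psm.engine.value,
            "peptidoform": m.peptidoform,
            "charge": m.psm.charge,
            "score": m.psm.score,
            "q_value": m.psm.q_value,
            "loc_score": "" if m.psm.loc_score is None else m.psm.loc_score,
            "provenance": m.provenance.value,
        }
        for m in merged
    ]
    pd.DataFrame(rows, columns=["run_id", "spectrum_id", "engine", "peptidoform",
                                "charge", "score", "q_value", "loc_score",
                                "provenance"]).to_csv(path, sep="\t", index=False)


def read_merged_table(path: str | Path) -> list[MergedPsm]:
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "spectrum_id": str})
    merged: list[MergedPsm] = []
    for row in df.itertuples(index=False):
        loc = row.loc_score
        psm = PsmRecord(
            run_id=str(row.run_id),
            spectrum_id=str(row.spectrum_id),
            engine=Engine(row.engine),
            peptidoform=str(row.peptidoform),
            charge=int(row.charge),
            score=float(row.score),
            q_value=float(row.q_value),
            loc_score=None if pd.isna(loc) else float(loc),
        )
        merged.append(MergedPsm(psm=psm, provenance=Provenance(row.provenance)))
    return merged


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths.

    Duplicate leaf labels are rejected: a Newick file with repeated tips
    cannot be read back unambiguously.
    """
    labels = [t.name for t in tree.tips()] if tree.children else [tree.name]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def read_unimod_map(path: str | Path) -> dict[str, list[str]]:
    """Read the modification-name → Unimod-class mapping TSV.

    Columns: mod_name, unimod_class.  A name listed under several classes
    maps to all of them (downstream grouping collapses those to "Other").
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"mod_name", "unimod_class"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mod_name, unimod_class")
    if df.empty:
        raise ValueError(f"{path}: empty modification class map")
    mapping: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(str(row.mod_name), []).append(str(row.unimod_class))
    return mapping


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
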