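"""Plain-text interchange: FASTA sequences, TSV mark/trace/neighborhood tables.

Formats
-------
* Sequences: FASTA (one record per duplex; topology encoded in the
  description as ``topology=circular|linear``).
* Marks: BED-like TSV with columns ``seq_id, linkage, strand(+/-), mark,
  mark_type(pt|base)`` — 0-based top coordinates; ``mark`` holds the
  stereochemistry (Rp/Sp) for PT marks or the cytosine modification for
  base marks; for base marks the linkage column carries the base column.
* Traces: TSV ``read_pos, template_col, call, hA, hC, hG, hT``.
* Neighborhoods: TSV ``genome_id, gene_index, label, strand``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import BaseMark, InputError, ModifiedDuplex, PTMark
from .digestion import CutEvent, Fragment
from .simulate import NeighborhoodTable, RunoffTrace, TraceRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_marks",
    "read_marks",
    "write_trace",
    "read_trace",
    "write_neighborhoods",
    "read_neighborhoods",
    "write_events",
    "write_fragments",
]

_STRAND_CODE = {"top": "+", "bottom": "-"}
_STRAND_NAME = {"+": "top", "-": "bottom"}


def write_fasta(duplexes: Iterable[ModifiedDuplex], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(d.top_seq), id=d.id, description=f"topology={d.topology}")
        for d in duplexes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ModifiedDuplex]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = "circular" if "topology=circular" in rec.description else "linear"
        out.append(ModifiedDuplex(id=rec.id, top_seq=str(rec.seq), topology=topology))
    return out


def write_marks(duplexes: Iterable[ModifiedDuplex], path: str | Path) -> None:
    rows = []
    for d in duplexes:
        for m in sorted(d.pt_marks):
            rows.append((d.id, m.linkage, _STRAND_CODE[m.strand], m.stereo, "pt"))
        for b in sorted(d.base_marks):
            rows.append((d.id, b.column, _STRAND_CODE[b.strand], b.mod, "base"))
    df = pd.DataFrame(rows, columns=["seq_id", "linkage", "strand", "mark", "mark_type"])
    df.to_csv(path, sep="\t", index=False)


def read_marks(path: str | Path, duplexes: Sequence[ModifiedDuplex]) -> list[ModifiedDuplex]:
    """Attach marks from a TSV to the matching duplexes (by id)."""
    df = pd.read_csv(path, sep="\t")
    by_id = {d.id: d for d in duplexes}
    for row in df.itertuples(index=False):
        d = by_id.get(row.seq_id)
        if d is None:
            raise InputError(f"marks reference unknown sequence {row.seq_id!r}")
        strand = _STRAND_NAME[row.strand]
        if row.mark_type == "pt":
            d.pt_marks.add(PTMark(strand, int(row.linkage), row.mark))
        elif row.mark_type == "base":
            d.base_marks.add(BaseMark(strand, int(row.linkage), row.mark))
        else:
            raise InputError(f"unknown mark_type {row.mark_type!r}")
    return list(duplexes)


def write_trace(trace: RunoffTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.read_pos, r.template_col, r.called_base, *r.heights)
            for r in trace.records
        ],
        columns=["read_pos", "template_col", "call", "hA", "hC", "hG", "hT"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_trace(
    path: str | Path,
    read_id: str = "trace",
    template_strand: str = "top",
    direction: int | None = None,
) -> RunoffTrace:
    df = pd.read_csv(path, sep="\t")
    records = [
        TraceRecord(
            int(r.read_pos), int(r.template_col), str(r.call),
            (float(r.hA), float(r.hC), float(r.hG), float(r.hT)),
        )
        for r in df.itertuples(index=False)
    ]
    if direction is None:
        direction = 1
        if len(records) > 1 and records[1].template_col < records[0].template_col:
            direction = -1
    primer = records[0].template_col if records else 0
    return RunoffTrace(read_id, template_strand, primer, direction, records)


def write_neighborhoods(tables: Iterable[NeighborhoodTable], path: str | Path) -> None:
    rows = [
        (t.genome_id, idx, label, strand)
        for t in tables
        for idx, label, strand in t.genes
    ]
    df = pd.DataFrame(rows, columns=["genome_id", "gene_index", "label", "strand"])
    df.to_csv(path, sep="\t", index=False)


def read_neighborhoods(path: str | Path) -> list[NeighborhoodTable]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for gid, grp in df.groupby("genome_id", sort=False):
        grp = grp.sort_values("gene_index")
        out.append(
            NeighborhoodTable(
                genome_id=str(gid),
                genes=[
                    (int(r.gene_index), str(r.label), str(r.strand))
                    for r in grp.itertuples(index=False)
                ],
            )
        )
    return out


def write_events(ensemble: Sequence[Sequence[CutEvent]], path: str | Path) -> None:
    rows = []
    for mol_id, events in enumerate(ensemble):
        for ev in events:
            rows.append(
                (
                    mol_id,
                    ev.site_ref.start if ev.site_ref else -1,
                    ev.kind,
                    -1 if ev.top_cut_linkage is None else ev.top_cut_linkage,
                    -1 if ev.bottom_cut_linkage is None else ev.bottom_cut_linkage,
                )
            )
    df = pd.DataFrame(
        rows, columns=["molecule_id", "site_start", "kind", "top_linkage", "bottom_linkage"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_fragments(frags: Sequence[Fragment], path: str | Path) -> None:
    rows = [
        (
            f.length,
            f.top_piece[0] if f.top_piece else -1,
            f.top_piece[1] if f.top_piece else -1,
            f.bottom_piece[0] if f.bottom_piece else -1,
            f.bottom_piece[1] if f.bottom_piece else -1,
            int(f.single_stranded),
        )
        for f in frags
    ]
    df = pd.DataFrame(
        rows,
        columns=["length", "top_start", "top_end", "bottom_start", "bottom_end", "single_stranded"],
    )
    df.to_csv(path, sep="\t", index=False)
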