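"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython; BED / bedGraph / TSV dialects are simple enough that
pandas handles them directly. All genomic intervals on disk are 0-based,
half-open; trio-table positions are 1-based (VCF convention).
"""
from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import GenomicInterval

if TYPE_CHECKING:  # pragma: no cover
    from .collapse import DepthTrack
    from .sd import DuplicationPair

TRIO_INDIVIDUALS = ("offspring", "father", "mother")
TRIO_SITE_COLUMNS = [
    "CHROM", "POS", "REF", "ALT",
    "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR",
]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bedgraph(tracks: dict[str, "DepthTrack"], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, track in tracks.items():
            w = track.bin_width
            for i, c in enumerate(track.counts):
                fh.write(f"{name}\t{i * w}\t{(i + 1) * w}\t{int(c)}\n")


def read_bedgraph(path: str | os.PathLike) -> dict[str, "DepthTrack"]:
    from .collapse import DepthTrack
    import numpy as np

    per: dict[str, list[tuple[int, int, int]]] = {}
    width = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            s, e = int(s), int(e)
            if width is None:
                width = e - s
            elif e - s != width:
                raise ValueError(f"non-uniform bin width at {chrom}:{s}-{e}")
            per.setdefault(chrom, []).append((s, e, int(float(v))))
    out = {}
    for chrom, rows in per.items():
        rows.sort()
        out[chrom] = DepthTrack(
            scaffold=chrom,
            bin_width=width or 100,
            counts=np.array([r[2] for r in rows], dtype=float),
        )
    return out


# -- SD pair tables (SEDEF-compatible column subset) --------------------------

SD_COLUMNS = ["chrA", "startA", "endA", "chrB", "startB", "endB", "identity", "length"]


def write_sd_table(pairs: Iterable["DuplicationPair"], path: str | os.PathLike) -> None:
    rows = [
        {
            "chrA": p.interval_a.scaffold, "startA": p.interval_a.start,
            "endA": p.interval_a.end,
            "chrB": p.interval_b.scaffold, "startB": p.interval_b.start,
            "endB": p.interval_b.end,
            "identity": round(p.identity, 6), "length": p.length,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=SD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sd_table(path: str | os.PathLike) -> list["DuplicationPair"]:
    from .sd import DuplicationPair

    df = pd.read_csv(path, sep="\t")
    return [
        DuplicationPair(
            interval_a=GenomicInterval(r.chrA, int(r.startA), int(r.endA)),
            interval_b=GenomicInterval(r.chrB, int(r.startB), int(r.endB)),
            identity=float(r.identity),
            length=int(r.length),
        )
        for r in df.itertuples()
    ]


# -- transcript models (GFF3 + spliced FASTA) ---------------------------------


def write_transcripts_gff3(transcripts, gff_path, fasta_path) -> None:
    """Write transcript models as GFF3 exon features plus spliced FASTA."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tr in transcripts:
            body_start, body_end = tr.exons[0][0], tr.exons[-1][1]
            fh.write(
                f"{tr.scaffold}\thapchar\tmRNA\t{body_start + 1}\t{body_end}\t.\t+\t.\t"
                f"ID={tr.transcript_id};Parent={tr.gene_id}\n"
            )
            for s, e in tr.exons:
                fh.write(
                    f"{tr.scaffold}\thapchar\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"Parent={tr.transcript_id}\n"
                )
    write_fasta({tr.transcript_id: tr.spliced_sequence for tr in transcripts},
                fasta_path)


def read_transcripts_gff3(gff_path, fasta_path) -> list:
    """Read transcript models from GFF3 exon features plus spliced FASTA."""
    from .genedup import TranscriptModel

    spliced = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if f[2] == "mRNA":
                meta[attrs["ID"]] = {
                    "scaffold": f[0], "gene": attrs.get("Parent", attrs["ID"]),
                    "exons": [],
                }
            elif f[2] == "exon":
                meta[attrs["Parent"]]["exons"].append((int(f[3]) - 1, int(f[4])))
    out = []
    for tr_id, m in meta.items():
        out.append(TranscriptModel(
            gene_id=m["gene"], transcript_id=tr_id, scaffold=m["scaffold"],
            exons=tuple(sorted(m["exons"])), spliced_sequence=spliced[tr_id],
        ))
    return out


# -- trio tables --------------------------------------------------------------


def write_trio_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """VCF-like TSV: site columns then one GT:DP:GQ:AD:EV column per individual."""
    out = table[TRIO_SITE_COLUMNS].copy()
    for ind in TRIO_INDIVIDUALS:
        out[ind] = (
            table[f"GT_{ind}"].astype(str)
            + ":" + table[f"DP_{ind}"].astype(int).astype(str)
            + ":" + table[f"GQ_{ind}"].astype(int).astype(str)
            + ":" + table[f"AD_{ind}"].astype(int).astype(str)
            + ":" + table[f"EV_{ind}"].astype(int).astype(str)
        )
    out.to_csv(path, sep="\t", index=False)


def read_trio_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for ind in TRIO_INDIVIDUALS:
        parts = df[ind].str.split(":", expand=True)
        df[f"GT_{ind}"] = parts[0]
        df[f"DP_{ind}"] = parts[1].astype(int)
        df[f"GQ_{ind}"] = parts[2].astype(int)
        df[f"AD_{ind}"] = parts[3].astype(int)
        df[f"EV_{ind}"] = parts[4].astype(int)
    return df.drop(columns=list(TRIO_INDIVIDUALS))


def read_vcf_trio(path: str | os.PathLike,
                  individuals: tuple[str, str, str] = TRIO_INDIVIDUALS) -> pd.DataFrame:
    """Read a standard VCF with GT:DP:GQ:AD FORMAT fields into the trio-table frame.

    Sample columns are mapped positionally onto (offspring, father, mother).
    AB is derivable downstream as AD_alt / DP; EV tokens are absent (-1).
    """
    import numpy as np

    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise ValueError("VCF missing #CHROM header line")
            f = dict(zip(header, line.split("\t")))
            info = dict(
                kv.split("=", 1) for kv in f.get("INFO", "").split(";") if "=" in kv
            )
            fmt = f["FORMAT"].split(":")
            row = {
                "CHROM": f["CHROM"], "POS": int(f["POS"]),
                "REF": f["REF"], "ALT": f["ALT"],
            }
            for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR"):
                row[key] = float(info[key]) if key in info else np.nan
            samples = header[header.index("FORMAT") + 1:]
            for ind, sample in zip(individuals, samples):
                vals = dict(zip(fmt, f[sample].split(":")))
                gt = vals.get("GT", "./.").replace("|", "/")
                ad = vals.get("AD", "0,0").split(",")
                row[f"GT_{ind}"] = gt
                row[f"DP_{ind}"] = int(vals.get("DP", 0) or 0)
                row[f"GQ_{ind}"] = int(vals.get("GQ", 0) or 0)
                row[f"AD_{ind}"] = int(ad[1]) if len(ad) > 1 else 0
                row[f"EV_{ind}"] = -1
            rows.append(row)
    return pd.DataFrame(rows)
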