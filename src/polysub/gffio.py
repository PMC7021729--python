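"""Light I/O helpers: FASTA (via Biopython), GFF3, BED, TSV conventions.

GFF3 coordinates are 1-based inclusive; BED is 0-based half-open.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: dict, path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _fmt_attributes(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write("\t".join([
                f["seqid"], f.get("source", "polysub"), f["type"],
                str(f["start"]), str(f["end"]), str(f.get("score", ".")),
                f.get("strand", "+"), str(f.get("phase", ".")),
                _fmt_attributes(f.get("attributes", {})),
            ]) + "\n")


def read_gff3(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            for kv in parts[8].split(";"):
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            rows.append({"seqid": parts[0], "source": parts[1], "type": parts[2],
                         "start": int(parts[3]), "end": int(parts[4]),
                         "score": parts[5], "strand": parts[6], "phase": parts[7],
                         **{f"attr_{k}": v for k, v in attrs.items()}})
    return pd.DataFrame(rows)


def write_bed(intervals: list[tuple], path: str) -> None:
    """intervals: (chrom, start, end[, name]) with 0-based half-open coords."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            row = {"chromosome": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                row["name"] = parts[3].strip()
            rows.append(row)
    return pd.DataFrame(rows)
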