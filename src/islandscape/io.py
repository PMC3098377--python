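"""Readers and writers for the on-disk formats.

FASTA via Biopython; BED6 and TSV via pandas. BED is 0-based half-open.
Tag BED records place the 5' end at ``start`` for + tags and at ``end - 1``
for - tags.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import Sensorgram
from .intervals import CpGIsland, GeneModel, GenomicInterval
from .profiles import MetaProfile, TagCollection

BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6[: df.shape[1]] + list(df.columns[6:])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def islands_to_bed(islands: Sequence[CpGIsland], path) -> None:
    rows = [
        {
            "chrom": i.chrom,
            "start": i.start,
            "end": i.end,
            "name": i.name or f"CGI_{k + 1}",
            "score": min(int(round(1000 * i.oe)), 1000),
            "strand": ".",
        }
        for k, i in enumerate(islands)
    ]
    write_bed(pd.DataFrame(rows, columns=BED6), path)


def islands_to_table(islands: Sequence[CpGIsland], path) -> None:
    pd.DataFrame(
        [
            {"chrom": i.chrom, "start": i.start, "end": i.end, "name": i.name,
             "gc": i.gc, "oe": i.oe, "length": len(i), "assoc": i.assoc}
            for i in islands
        ]
    ).to_csv(path, sep="\t", index=False)


def genes_to_bed(genes: Sequence[GeneModel], path) -> None:
    rows = [
        {"chrom": g.chrom, "start": g.start, "end": g.end, "name": g.name,
         "score": int(g.expressed), "strand": g.strand}
        for g in genes
    ]
    write_bed(pd.DataFrame(rows, columns=BED6), path)


def read_genes_bed(path) -> list[GeneModel]:
    df = read_bed(path)
    return [
        GeneModel(r.chrom, int(r.start), int(r.end), r.strand, str(r.name),
                  expressed=bool(int(r.score)))
        for r in df.itertuples()
    ]


def tags_to_bed(tags: TagCollection, path, read_length: int = 36) -> None:
    rows = []
    for chrom, (pos, strand) in tags.tags.items():
        start = np.where(strand > 0, pos, pos - read_length + 1)
        start = np.maximum(start, 0)
        for s, st in zip(start, strand):
            rows.append((chrom, int(s), int(s) + read_length, tags.name, 0,
                         "+" if st > 0 else "-"))
    pd.DataFrame(rows, columns=BED6).to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path, name: str, fragment_length: int = 150) -> TagCollection:
    df = read_bed(path)
    tags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom"):
        plus = grp["strand"].to_numpy() == "+"
        five = np.where(plus, grp["start"].to_numpy(), grp["end"].to_numpy() - 1)
        tags[str(chrom)] = (five.astype(np.int64), np.where(plus, 1, -1).astype(np.int8))
    return TagCollection(name=name, fragment_length=fragment_length, tags=tags)


def methylome_to_tsv(methylome, path) -> None:
    methylome.to_frame().to_csv(path, sep="\t", index=False)


def profile_to_tsv(profile: MetaProfile, path) -> None:
    pd.DataFrame(
        {"bin": profile.positions, "value": profile.values, "n_anchors": profile.n_anchors}
    ).to_csv(path, sep="\t", index=False)


def density_to_bedgraph(chrom: str, start: int, values: np.ndarray, bin_size: int, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if v != 0:
                s = start + i * bin_size
                fh.write(f"{chrom}\t{s}\t{s + bin_size}\t{v:.6g}\n")


def peaks_to_bed(peaks, path) -> None:
    rows = []
    for k, p in enumerate(peaks):
        score = 0 if p.q_value <= 0 else min(int(round(-10 * np.log10(max(p.q_value, 1e-300)))), 1000)
        rows.append((p.chrom, p.start, p.end, f"peak_{k + 1}", score, ".",
                     f"{p.fold:.4g}", f"{p.p_value:.4g}", f"{p.q_value:.4g}", p.summit))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def sensorgrams_to_tsv(sensorgrams: Iterable[Sensorgram], path) -> None:
    frames = [
        pd.DataFrame(
            {"time": sg.times, "concentration": sg.conc, "response": sg.response,
             "t_assoc": sg.t_assoc}
        )
        for sg in sensorgrams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_sensorgrams_tsv(path) -> list[Sensorgram]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for conc, grp in df.groupby("concentration", sort=True):
        out.append(
            Sensorgram(
                conc=float(conc),
                times=grp["time"].to_numpy(dtype=float),
                response=grp["response"].to_numpy(dtype=float),
                t_assoc=float(grp["t_assoc"].iloc[0]),
            )
        )
    return out


def report_to_json(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict() if hasattr(report, "to_dict") else report, fh, indent=2)
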