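"""Readers and writers for the tabular dialects the pipeline touches.

All coordinates on disk are 0-based half-open (BED convention); 1-based
sources must be converted before they reach these readers.  Every reader
validates against the schema it declares and reports the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .genome_model import (
    STATE_VOCABULARIES,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ProbeSet,
    SegmentationStack,
    TECopy,
)

logger = logging.getLogger(__name__)

# RepeatMasker classes excluded from all TE analyses
NON_TE_CLASSES = {"Simple_repeat", "Low_complexity", "Satellite"}


def _data_lines(path: Path) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(
    path: str | Path, chrom_sizes: Optional[Mapping[str, int]] = None
) -> List[GenomicInterval]:
    """Read a BED3+ file into intervals; column 5 (score), if present, as value."""
    path = Path(path)
    out: List[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
        if start >= end or start < 0:
            raise ValueError(
                f"{path}:{lineno}: invalid interval [{start}, {end}) "
                "(0-based half-open; start < end required)"
            )
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ValueError(f"{path}:{lineno}: end {end} exceeds chromosome length")
        value = None
        if len(fields) >= 5:
            try:
                value = float(fields[4])
            except ValueError:
                value = None
        out.append(GenomicInterval(chrom, start, end, value))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.value is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{iv.value:g}\n")


def read_signal_track(path: str | Path) -> List[GenomicInterval]:
    """BED4 interval+value track (chrom, start, end, value)."""
    path = Path(path)
    out: List[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: signal track needs 4 columns")
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed value column") from exc
        start, end = int(fields[1]), int(fields[2])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        out.append(GenomicInterval(fields[0], start, end, value))
    return out


def read_segmentation(
    paths: Mapping[str, str | Path], model: str
) -> SegmentationStack:
    """Read 4-column state BEDs (chrom, start, end, state), one per epigenome."""
    if model not in STATE_VOCABULARIES:
        raise ValueError(f"unknown segmentation model {model!r}")
    vocab = set(STATE_VOCABULARIES[model])
    epigenomes: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    for eid, path in paths.items():
        path = Path(path)
        segs: List[Tuple[GenomicInterval, str]] = []
        for lineno, fields in _data_lines(path):
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: segmentation needs 4 columns")
            state = fields[3]
            if state not in vocab:
                raise ValueError(
                    f"{path}:{lineno}: state {state!r} not in the {model} vocabulary"
                )
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            segs.append((GenomicInterval(fields[0], start, end), state))
        epigenomes[eid] = segs
    return SegmentationStack(model=model, epigenomes=epigenomes)


def write_segmentation(stack: SegmentationStack, directory: str | Path) -> Dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for eid, segs in stack.epigenomes.items():
        p = directory / f"{eid}.{stack.model}.bed"
        with open(p, "w") as fh:
            for iv, state in segs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")
        out[eid] = p
    return out


def read_gene_models(path: str | Path) -> List[GeneModel]:
    """Tab-separated with header: gene_id, chrom, strand, txStart, txEnd[, aliases]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "strand", "txStart", "txEnd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        aliases: Tuple[str, ...] = ()
        if hasattr(row, "aliases") and isinstance(row.aliases, str) and row.aliases:
            aliases = tuple(row.aliases.split(","))
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                body=GenomicInterval(row.chrom, int(row.txStart), int(row.txEnd)),
                aliases=aliases,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "txStart": g.body.start,
            "txEnd": g.body.end,
            "aliases": ",".join(g.aliases),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_te_table(path: str | Path) -> List[TECopy]:
    """TSV with header chrom, start, end, subfamily, family, class.

    Simple repeats, low-complexity and satellite records are dropped (with a
    logged count): they are not transposable elements.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "subfamily", "family", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: TE table missing columns {sorted(missing)}")
    dropped = int(df["class"].isin(NON_TE_CLASSES).sum())
    if dropped:
        logger.info("%s: dropped %d simple/low-complexity repeat rows", path, dropped)
    df = df[~df["class"].isin(NON_TE_CLASSES)].rename(columns={"class": "te_class"})
    return [
        TECopy(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            subfamily=r.subfamily,
            family=r.family,
            te_class=r.te_class,
        )
        for r in df.itertuples(index=False)
    ]


def write_te_table(tes: Iterable[TECopy], path: str | Path) -> None:
    rows = [
        {
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "subfamily": t.subfamily,
            "family": t.family,
            "class": t.te_class,
        }
        for t in tes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probe_manifest(path: str | Path, platform: str = "synthetic") -> ProbeSet:
    """Probe manifest: TSV with header probe_id, chrom, pos (or the Illumina
    CSV column subset IlmnID, CHR, MAPINFO, where MAPINFO is 1-based)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str)
        if not {"IlmnID", "CHR", "MAPINFO"} <= set(df.columns):
            raise ValueError(f"{path}: manifest CSV needs IlmnID, CHR, MAPINFO")
        df = pd.DataFrame(
            {
                "probe_id": df["IlmnID"],
                "chrom": df["CHR"].map(lambda c: c if str(c).startswith("chr") else f"chr{c}"),
                "pos": df["MAPINFO"].astype(int) - 1,  # 1-based -> 0-based
            }
        )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
        if not {"probe_id", "chrom", "pos"} <= set(df.columns):
            raise ValueError(f"{path}: manifest needs probe_id, chrom, pos columns")
    positions: Dict[str, np.ndarray] = {}
    ids: Dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom"):
        positions[str(chrom)] = grp["pos"].to_numpy(dtype=np.int64)
        ids[str(chrom)] = grp["probe_id"].to_numpy(dtype=object)
    return ProbeSet(platform=platform, positions=positions, probe_ids=ids)


def write_probe_manifest(probes: ProbeSet, path: str | Path) -> None:
    rows = []
    for chrom in sorted(probes.positions):
        for pid, pos in zip(probes.probe_ids[chrom], probes.positions[chrom]):
            rows.append({"probe_id": pid, "chrom": chrom, "pos": int(pos)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rpkm_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample RPKM table (first column gene id, remaining numeric)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: RPKM matrix has no sample columns")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: RPKM values must be >= 0")
    return df.astype(float)


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Probe x sample beta matrix; values in [0,1] or missing."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    vals = df.to_numpy()
    ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
    if not ok.all():
        raise ValueError(f"{path}: beta values outside [0, 1]")
    return df


def intervals_to_bed_df(ivs: Iterable[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in ivs],
        columns=["chrom", "start", "end"],
    )


def interval_set_to_bed(ivset: IntervalSet, path: str | Path) -> None:
    write_bed(ivset.intervals(), path)
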