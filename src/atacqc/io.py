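"""Text-format I/O: BED-like fragment files, peak files, GTF TSS references.

All readers consume uncompressed tab-separated text.  GTF input (1-based,
inclusive) is converted to 0-based half-open at the parser boundary; every
other format is already BED-family.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .model import (
    MAX_FRAGMENT_LENGTH,
    DEFAULT_READ_LENGTH,
    FragmentLibrary,
    GenomeLayout,
    PeakSet,
    TssReference,
)

logger = logging.getLogger("atacqc")

# gene/transcript types whose TSSs are retained, mirroring the filtering
# used by common single-cell ATAC pipelines
TSS_TYPE_WHITELIST = frozenset({
    "protein_coding", "lncRNA",
    "IG_C_gene", "IG_D_gene", "IG_J_gene", "IG_LV_gene", "IG_V_gene",
    "IG_V_pseudogene", "IG_J_pseudogene", "IG_C_pseudogene",
    "TR_C_gene", "TR_D_gene", "TR_J_gene", "TR_V_gene",
    "TR_V_pseudogene", "TR_J_pseudogene",
})
TSS_TAG_BLACKLIST = frozenset({"readthrough_transcript", "PAR"})

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_fragments(
    path,
    layout: GenomeLayout,
    read_length: int = DEFAULT_READ_LENGTH,
) -> FragmentLibrary:
    """Load aligned fragments from a BED3+ file.

    Records on chromosomes absent from ``layout`` or longer than
    2000 bp are rejected with a logged warning; ``start >= end`` is a hard
    error naming the offending line.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            if chrom not in layout:
                logger.warning(
                    "%s:%d: unknown chromosome %r, record rejected",
                    path, lineno, chrom,
                )
                continue
            if end - start > MAX_FRAGMENT_LENGTH:
                logger.warning(
                    "%s:%d: fragment length %d exceeds %d, record rejected",
                    path, lineno, end - start, MAX_FRAGMENT_LENGTH,
                )
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    records = pd.DataFrame({
        "chrom": np.asarray(chroms, dtype=object),
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
    })
    return FragmentLibrary(records=records, layout=layout, read_length=read_length)


def write_fragments(lib: FragmentLibrary, path) -> None:
    """Write fragment records as BED3, preserving order."""
    with open(path, "w") as fh:
        for chrom, start, end in zip(
            lib.records["chrom"], lib.records["start"], lib.records["end"]
        ):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_peaks(path) -> PeakSet:
    """Read BED3+/narrowPeak intervals; column 4 (if present) becomes names.

    Comma-joined tokens in column 4 are parsed into condition label sets.
    """
    chroms, starts, ends, names = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            chroms.append(fields[0])
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            names.append(fields[3] if len(fields) > 3 else ".")
    df = pd.DataFrame({
        "chrom": np.asarray(chroms, dtype=object),
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
        "name": names,
    })
    df["labels"] = [
        frozenset(n.split(",")) if n not in (".", "") else frozenset()
        for n in names
    ]
    return PeakSet(df)


def write_peaks_bed(peaks: PeakSet, path, header: str | None = None) -> None:
    """Write intervals as BED4 with comma-joined label tokens in column 4."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        has_labels = "labels" in peaks.df.columns
        for _, row in peaks.df.iterrows():
            if has_labels and row["labels"]:
                name = ",".join(sorted(row["labels"]))
            else:
                name = row.get("name", ".") if hasattr(row, "get") else "."
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\n")


def write_narrowpeak(peaks: PeakSet, path, header: str | None = None) -> None:
    """Write a 10-column narrowPeak file.

    Uses ``summit`` (absolute coordinate), ``score``, ``pvalue`` and
    ``qvalue`` columns when present; missing statistics become -1 per the
    ENCODE convention.
    """
    df = peaks.df
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for i, row in df.iterrows():
            name = row["name"] if "name" in df.columns else f"peak_{i + 1}"
            score = int(row["score"]) if "score" in df.columns else 0
            sig = row["signal"] if "signal" in df.columns else 0.0
            pval = row["pvalue"] if "pvalue" in df.columns else -1.0
            qval = row["qvalue"] if "qvalue" in df.columns else -1.0
            summit = (
                int(row["summit"]) - int(row["start"])
                if "summit" in df.columns
                else -1
            )
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t"
                f"{score}\t.\t{sig:.4f}\t{pval:.4f}\t{qval:.4f}\t{summit}\n"
            )


def _parse_gtf_attributes(attr: str, path, lineno: int) -> dict[str, list[str]]:
    pairs = _ATTR_RE.findall(attr)
    if not pairs and attr.strip() not in ("", "."):
        raise ValueError(f"{path}:{lineno}: malformed GTF attribute column")
    out: dict[str, list[str]] = {}
    for key, value in pairs:
        out.setdefault(key, []).append(value)
    return out


def build_tss_reference(path) -> TssReference:
    """Derive a TSS reference from GTF transcript records.

    Keeps the most upstream base of each transcript (start for ``+``,
    ``end - 1`` for ``-`` after conversion to half-open), retains only
    transcripts whose gene type AND transcript type are both in the
    whitelist, and drops transcripts tagged ``readthrough_transcript`` or
    ``PAR``.  Both ``*_type`` and ``*_biotype`` attribute spellings are
    accepted.  Duplicate (chrom, pos, strand) entries collapse.
    """
    chroms, positions, strands = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "transcript":
                continue
            chrom, start_s, end_s, strand = (
                fields[0], fields[3], fields[4], fields[6],
            )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gtf_attributes(fields[8], path, lineno)
            gene_type = attrs.get("gene_type", attrs.get("gene_biotype", []))
            tx_type = attrs.get(
                "transcript_type", attrs.get("transcript_biotype", [])
            )
            if not (set(gene_type) & TSS_TYPE_WHITELIST):
                continue
            if not (set(tx_type) & TSS_TYPE_WHITELIST):
                continue
            if set(attrs.get("tag", [])) & TSS_TAG_BLACKLIST:
                continue
            start1, end1 = int(start_s), int(end_s)
            # GTF is 1-based inclusive; half-open interval is [start1-1, end1)
            pos = start1 - 1 if strand == "+" else end1 - 1
            chroms.append(chrom)
            positions.append(pos)
            strands.append(strand)
    return TssReference.from_arrays(chroms, positions, strands)


def write_tss_bed(tss: TssReference, path) -> None:
    """Serialize a TSS reference as BED6 of single-base intervals."""
    with open(path, "w") as fh:
        for _, row in tss.df.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['pos'] + 1}\t.\t0\t"
                f"{row['strand']}\n"
            )


def read_tss_bed(path) -> TssReference:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return TssReference.from_arrays(
        df["chrom"].astype(object), df["start"], df["strand"].astype(object)
    )
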