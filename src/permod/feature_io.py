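"""Readers and writers for the external formats the toolkit touches.

Per-base per-read feature tables (tab-separated), modified-base alignments
(SAM/BAM with MM/ML tags), bedMethyl site tables, exon annotations
(GFF3/BED12) and the per-read polyA-length / isoform-assignment tables
produced by tailfindr-like and Isoquant-like tools.

All coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on read.  Direct RNA reads are sense-stranded, so bases and k-mers
are always reported in transcript sense.
"""

from __future__ import annotations

import array
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import (
    ConsistencyError,
    FormatError,
    TagConsistencyError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# feature-table schemas
# ---------------------------------------------------------------------------

#: identity columns shared by both chemistries
ID_COLUMNS = ["read_id", "ref_id", "pos", "strand", "ref_base", "kmer", "sample"]

#: the 9 per-base signal/basecall features of the RNA002 chemistry:
#: signal intensity, basecaller modification probability, dwell time at the
#: central base and 10 bases upstream, and the 5 trace values (reference
#: base + each canonical base).
FEATURES_RNA002 = ["SI", "MP", "DT", "DT10", "TR", "TA", "TC", "TG", "TT"]

#: per-position feature block for the RNA004 chemistry (13 features, taken
#: at read offsets -1, 0 and +1 relative to the candidate base = 39 total):
#: SI mean/sd, two dwell times, basecaller probabilities of A/C/G/T(U)/stay
#: and of the reference base, and the 3 top-ranked k-mers of the model.
_RNA004_BLOCK = [
    "SI_mean", "SI_sd", "DT0", "DT10",
    "pA", "pC", "pG", "pT", "pN", "pRef",
    "kmer1", "kmer2", "kmer3",
]
FEATURES_RNA004 = [
    f"{name}_{tag}" for tag in ("m1", "c0", "p1") for name in _RNA004_BLOCK
]

#: columns whose values must lie in [0, 1]
_PROB_COLUMNS = {
    "rna002": ["MP", "TR", "TA", "TC", "TG", "TT"],
    "rna004": [c for c in FEATURES_RNA004 if c.rsplit("_", 1)[0].startswith("p")],
}
_NONNEG_COLUMNS = {
    "rna002": ["DT", "DT10"],
    "rna004": [c for c in FEATURES_RNA004 if c.rsplit("_", 1)[0].startswith("DT")],
}

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def feature_columns(mode: str) -> list[str]:
    """Feature column names for a chemistry mode ('rna002' or 'rna004')."""
    if mode == "rna002":
        return list(FEATURES_RNA002)
    if mode == "rna004":
        return list(FEATURES_RNA004)
    raise ValueError(f"unknown mode {mode!r}; expected 'rna002' or 'rna004'")


def read_feature_table(path, mode: str = "rna002", on_bad: str = "raise") -> pd.DataFrame:
    """Read a per-base per-read feature table.

    Parameters
    ----------
    path
        Tab-separated file with the identity columns and the feature
        columns of the requested chemistry.
    mode
        'rna002' (9 features per base) or 'rna004' (39 features per base).
    on_bad
        'raise' aborts at the first row violating a bound; 'skip' drops such
        rows and records ``(line_number, reason)`` tuples in
        ``df.attrs['rejected']``.

    Returns
    -------
    DataFrame with one row per (read, position).
    """
    feats = feature_columns(mode)
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref_id": str})
    missing = [c for c in ID_COLUMNS + feats if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    # header is line 1, first data row is line 2
    lines = df.index.to_numpy() + 2
    bad = np.zeros(len(df), dtype=bool)
    reasons: list[tuple[int, str]] = []

    def _flag(mask: np.ndarray, reason_fmt: str, col: str) -> None:
        for ln in lines[mask & ~bad]:
            reasons.append((int(ln), reason_fmt.format(col=col)))
        bad[:] = bad | mask

    for col in _PROB_COLUMNS[mode]:
        vals = pd.to_numeric(df[col], errors="coerce")
        _flag((vals < 0) | (vals > 1) | vals.isna().to_numpy(),
              "{col} outside [0, 1]", col)
    for col in _NONNEG_COLUMNS[mode]:
        vals = pd.to_numeric(df[col], errors="coerce")
        _flag((vals < 0) | vals.isna().to_numpy(), "{col} negative", col)
    if mode == "rna002" and len(df):
        kmer_ok = df["kmer"].str.len().eq(7) & (
            df["kmer"].str[3] == df["ref_base"].str.replace("U", "T")
        )
        _flag(~kmer_ok.to_numpy(), "kmer not centered on ref_base", "kmer")

    if reasons:
        reasons.sort()
        if on_bad == "raise":
            ln, why = reasons[0]
            raise ValidationError(f"{path}: line {ln}: {why}")
        df = df.loc[~bad].reset_index(drop=True)
    df.attrs["rejected"] = reasons
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table as TSV (stable column order, '%.6g' floats)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# modProb byte encoding (SAM ML tag convention)
# ---------------------------------------------------------------------------

def encode_modprob(p):
    """Encode probability in [0, 1] as the 256-bin ML byte.

    ``byte = min(floor(p * 256), 255)`` so that byte *b* stands for the
    interval [b/256, (b+1)/256).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("modification probability outside [0, 1]")
    enc = np.minimum(np.floor(arr * 256), 255).astype(np.uint8)
    return enc if arr.ndim else int(enc)


def decode_modprob(byte):
    """Decode an ML byte to the midpoint probability (byte + 0.5) / 256."""
    arr = np.asarray(byte)
    if np.any((arr < 0) | (arr > 255)):
        raise ValueError("ML byte outside [0, 255]")
    dec = (arr + 0.5) / 256.0
    return dec if arr.ndim else float(dec)


# ---------------------------------------------------------------------------
# modified-base alignments (MM/ML)
# ---------------------------------------------------------------------------

#: columns of a per-read per-base call table
CALL_COLUMNS = ["read_id", "ref_id", "pos", "strand", "base", "mod_prob"]


def _check_mm_ml(read: pysam.AlignedSegment) -> None:
    if not read.has_tag("MM"):
        return
    mm = read.get_tag("MM")
    n_mm = sum(
        len([d for d in item.split(",")[1:] if d != ""])
        for item in mm.rstrip(";").split(";")
        if item
    )
    n_ml = len(read.get_tag("ML")) if read.has_tag("ML") else 0
    if n_mm != n_ml:
        raise TagConsistencyError(
            f"read {read.query_name}: MM lists {n_mm} positions but ML has {n_ml} entries"
        )


def read_modbam(path, mod_code: str = "a", canonical: str = "A") -> pd.DataFrame:
    """Extract per-read per-base modification calls from a SAM/BAM file.

    One row per canonical base with a probability entry in the MM/ML tags.
    Reference coordinates come from the alignment: insertions are skipped
    and deletions produce no call.  Bases are reported in transcript sense
    (an adenosine of a reverse-aligned read is still 'A', on strand '-').

    ``df.attrs['skipped_unmapped']`` counts unmapped reads that were ignored.
    """
    rows = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped:
                skipped += 1
                continue
            _check_mm_ml(read)
            mods = read.modified_bases  # {(canon, strand, code): [(qpos, qual)]}
            if not mods:
                continue
            qual_by_qpos = {}
            for (canon, _mstrand, code), entries in mods.items():
                if canon == canonical and str(code) == mod_code:
                    qual_by_qpos.update(entries)
            if not qual_by_qpos:
                continue
            strand = "-" if read.is_reverse else "+"
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if qpos in qual_by_qpos:
                    rows.append((
                        read.query_name, read.reference_name, rpos, strand,
                        canonical, decode_modprob(qual_by_qpos[qpos]),
                    ))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df.attrs["skipped_unmapped"] = skipped
    return df


def write_modbam(calls: pd.DataFrame, template_path, out_path,
                 mod_code: str = "a", canonical: str = "A") -> None:
    """Write calls into MM/ML tags on template alignments.

    Every call must sit at a reference position aligned in its read's
    template alignment, else a :class:`ConsistencyError` is raised.  Output
    is SAM or BAM depending on the ``out_path`` extension.
    """
    by_read: dict[str, pd.DataFrame] = {
        rid: grp for rid, grp in calls.groupby("read_id")
    } if len(calls) else {}
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(template_path), check_sq=False) as tpl, \
            pysam.AlignmentFile(str(out_path), mode, template=tpl) as out:
        for read in tpl:
            grp = by_read.get(read.query_name)
            if grp is None or read.is_unmapped:
                out.write(read)
                continue
            ref2q = {r: q for q, r in read.get_aligned_pairs(matches_only=True)}
            unaligned = set(grp["pos"]) - set(ref2q)
            if unaligned:
                raise ConsistencyError(
                    f"read {read.query_name}: call at reference position(s) "
                    f"{sorted(unaligned)[:3]} not aligned in template"
                )
            seq = read.query_sequence
            # MM deltas refer to the original (pre-alignment) read orientation
            if read.is_reverse:
                oseq = _revcomp(seq)
                opos = {p: len(seq) - 1 - ref2q[p] for p in grp["pos"]}
            else:
                oseq = seq
                opos = {p: ref2q[p] for p in grp["pos"]}
            entries = sorted(
                (opos[p], encode_modprob(mp))
                for p, mp in zip(grp["pos"], grp["mod_prob"])
            )
            canon_idx = [i for i, b in enumerate(oseq) if b in (canonical, "U" if canonical == "T" else canonical)]
            rank = {q: i for i, q in enumerate(canon_idx)}
            deltas, last = [], -1
            for q, _b in entries:
                if q not in rank:
                    raise ConsistencyError(
                        f"read {read.query_name}: call at non-{canonical} read position {q}"
                    )
                deltas.append(rank[q] - last - 1)
                last = rank[q]
            read.set_tag("MM", f"{canonical}+{mod_code}?," +
                         ",".join(map(str, deltas)) + ";")
            read.set_tag("ML", array.array("B", [b for _q, b in entries]))
            out.write(read)


# ---------------------------------------------------------------------------
# bedMethyl
# ---------------------------------------------------------------------------

def write_bedmethyl(site_calls: pd.DataFrame, path, mod_code: str = "a") -> None:
    """Write site calls as a 9+2-column bedMethyl table.

    Columns: chrom, start, end, mod code, min(coverage, 1000), strand,
    start, end, color, coverage, frequency in percent with one decimal.
    """
    with open(path, "w") as fh:
        for row in site_calls.itertuples(index=False):
            start, end = int(row.pos), int(row.pos) + 1
            freq = 100.0 * row.n_modified / row.coverage
            fh.write(
                f"{row.chrom}\t{start}\t{end}\t{mod_code}\t"
                f"{min(int(row.coverage), 1000)}\t{row.strand}\t{start}\t{end}\t"
                f"0,0,0\t{int(row.coverage)}\t{freq:.1f}\n"
            )


def read_bedmethyl(path) -> pd.DataFrame:
    """Read a bedMethyl table back into a site-call frame."""
    names = ["chrom", "start", "end", "mod_code", "score", "strand",
             "tstart", "tend", "color", "coverage", "frequency"]
    df = pd.read_csv(path, sep="\t", names=names)
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos": df["start"].astype(int),
        "strand": df["strand"],
        "coverage": df["coverage"].astype(int),
        "n_modified": np.rint(df["frequency"] / 100.0 * df["coverage"]).astype(int),
        "frequency": df["frequency"] / 100.0,
    })
    return out


# ---------------------------------------------------------------------------
# exon annotations
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """Ordered exon structure of one transcript (0-based half-open)."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    chrom: str = ""

    def validate(self) -> None:
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        self.exons = ex


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_exon_annotation(path) -> dict[str, Transcript]:
    """Read exon structures from GFF3 or BED12.

    GFF3 exon features need a ``Parent`` transcript attribute; exons without
    one are skipped (counted in the returned dict's ``.skipped`` attribute is
    not possible on a dict, so a warning count is attached to each call via
    the module logger-free convention of simply dropping them).
    """
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path) -> dict[str, Transcript]:
    transcripts: dict[str, Transcript] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f[:9]
            a = _parse_gff_attributes(attrs)
            if ftype in ("mRNA", "transcript"):
                tid = a.get("ID")
                if tid:
                    gene_of[tid] = a.get("Parent", a.get("gene_id", tid))
            elif ftype == "exon":
                parent = a.get("Parent")
                if not parent:
                    continue  # exon without parent transcript: skipped
                for tid in parent.split(","):
                    tr = transcripts.setdefault(
                        tid, Transcript(tid, gene_of.get(tid, tid), strand, [], chrom)
                    )
                    # GFF3 is 1-based closed
                    tr.exons.append((int(start) - 1, int(end)))
    for tr in transcripts.values():
        tr.gene_id = gene_of.get(tr.transcript_id, tr.gene_id)
        tr.validate()
    return transcripts


def _read_bed12(path) -> dict[str, Transcript]:
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: BED12 requires 12 columns, got {len(f)}")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), f[2], f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + st, start + st + sz) for st, sz in zip(starts, sizes)]
            tr = Transcript(name, name, strand, exons, chrom)
            tr.validate()
            transcripts[name] = tr
    return transcripts


# ---------------------------------------------------------------------------
# per-read auxiliary tables
# ---------------------------------------------------------------------------

#: isoform-assignment classes that mark a read as unambiguously assigned
UNIQUE_ASSIGNMENT_CLASSES = frozenset({"unique", "fsm", "mono_exon_match"})


def read_polya_table(path) -> pd.DataFrame:
    """Read a per-read polyA-length table (read_id, polya_length in nt)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    for col in ("read_id", "polya_length"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column: {col}")
    if (df["polya_length"] < 0).any():
        raise ValidationError(f"{path}: negative polya_length")
    return df


def read_isoform_table(path) -> pd.DataFrame:
    """Read a per-read isoform-assignment table (read_id, transcript_id, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("read_id", "transcript_id", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column: {col}")
    if df["read_id"].duplicated().any():
        raise ValidationError(f"{path}: multiple assignments for one read")
    return df
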