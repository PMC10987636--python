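"""Quality filtering of targeted scar libraries down to a diploid allele table.

The stages mirror how a targeted 10x scar amplicon library is processed after
alignment: reads are kept only for cell barcodes that passed transcriptome QC
and only if they start with the gene-specific primer, sequences are truncated
to 75 nt, a 40-base sequence-ID around the cut site is extracted per read,
reads are collapsed to UMI counts, and finally each (cell, target) is reduced
to at most two alleles.  Because each target gene is diploid, at most two
valid sequences (wildtype or scar) can be present in a cell; barcodes showing
more than two abundant sequences at more than one target are removed as
putative doublets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: width of the sequence-ID window on each side of the cut site
DEFAULT_FLANK = 20

#: reads are truncated to this length after primer matching
READ_TRUNCATION = 75

# numeric tolerance when comparing cumulative UMI counts against a fractional
# threshold; makes "exactly 80% of the total" count as reached despite binary
# floating point (0.8 * 100 is not representable exactly)
_FRACTION_EPS = 1e-9

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# pysam numeric CIGAR operation codes -> characters
_PYSAM_OPS = "MIDNSHP=XB"


@dataclass(frozen=True)
class ReadRecord:
    """One scar read: cell barcode, target gene, UMI, and read sequence."""

    cell: str
    target: str
    umi: str
    sequence: str


@dataclass(frozen=True)
class TargetReference:
    """Amplicon reference for one target gene with its Cas9 cut site.

    ``cut_site`` is 0-based; the sequence-ID window spans
    ``[cut_site - flank, cut_site + flank)`` on the reference.
    """

    target: str
    sequence: str
    cut_site: int
    primer: str = ""

    def __post_init__(self):
        if not 0 <= self.cut_site < len(self.sequence):
            raise ValueError(
                f"cut_site {self.cut_site} outside reference of length {len(self.sequence)}"
            )
        if self.primer and not self.sequence.startswith(self.primer):
            raise ValueError(f"primer for {self.target!r} is not a prefix of its reference")

    def window(self, flank: int = DEFAULT_FLANK) -> tuple[int, int]:
        return max(0, self.cut_site - flank), min(len(self.sequence), self.cut_site + flank)

    def wildtype_id(self, flank: int = DEFAULT_FLANK) -> str:
        """The sequence-ID of an unedited allele: the reference window itself."""
        lo, hi = self.window(flank)
        return self.sequence[lo:hi]


@dataclass
class AlleleTable:
    """Diploid allele layer: per (cell, target) at most two retained sequence-IDs.

    Attributes
    ----------
    retained
        Long table with columns ``cell, target, seq_id, umi_count``.
    flagged
        ``cell, target`` pairs where more than ``max_alleles`` sequences
        contributed to the top fraction of UMIs; their data is dropped.
    doublets
        Cell barcodes removed entirely because more than one target was
        flagged.
    """

    retained: pd.DataFrame
    flagged: pd.DataFrame
    doublets: list[str] = field(default_factory=list)

    @property
    def cells(self) -> list[str]:
        return sorted(self.retained["cell"].unique())

    def ids_by_cell(self, target: str) -> dict[str, frozenset[str]]:
        """Map cell -> retained sequence-IDs on one target."""
        sub = self.retained[self.retained["target"] == target]
        return {cell: frozenset(grp["seq_id"]) for cell, grp in sub.groupby("cell", sort=True)}


def make_references(
    sequences: Mapping[str, str],
    cut_sites: Mapping[str, int],
    primer_length: int = 20,
) -> dict[str, TargetReference]:
    """Assemble :class:`TargetReference` objects from FASTA sequences and BED cut sites.

    The gene-specific primer is taken as the first ``primer_length`` bases of
    each amplicon reference.
    """
    refs = {}
    for target, seq in sequences.items():
        if target not in cut_sites:
            raise KeyError(f"no cut site provided for target {target!r}")
        refs[target] = TargetReference(
            target=target,
            sequence=seq,
            cut_site=cut_sites[target],
            primer=seq[:primer_length],
        )
    return refs


def preprocess_reads(
    reads: Iterable[ReadRecord],
    valid_barcodes: set[str],
    refs: Mapping[str, TargetReference],
    truncate_to: int = READ_TRUNCATION,
) -> Iterator[ReadRecord]:
    """Keep reads with a QC-passing barcode that start with the target primer.

    Kept sequences are truncated to ``truncate_to`` nucleotides (a cap, not
    padding).  Reads for unknown targets are logged and skipped.  Order is
    preserved.
    """
    for read in reads:
        ref = refs.get(read.target)
        if ref is None:
            logger.warning("read for unknown target %r skipped (cell %s)", read.target, read.cell)
            continue
        if read.cell not in valid_barcodes:
            continue
        if not read.sequence.startswith(ref.primer):
            continue
        yield replace(read, sequence=read.sequence[:truncate_to])


def _normalize_cigar(cigar) -> list[tuple[str, int]]:
    if isinstance(cigar, str):
        ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
        if not ops:
            raise ValueError(f"could not parse CIGAR string {cigar!r}")
        return ops
    out = []
    for op, n in cigar:
        if isinstance(op, int):  # pysam cigartuples order is (op, length)
            op = _PYSAM_OPS[op]
        out.append((op, int(n)))
    return out


def scar_id_from_alignment(
    query: str,
    cigar,
    ref_start: int,
    cut_site: int,
    flank: int = DEFAULT_FLANK,
) -> str | None:
    """Extract the sequence-ID from one aligned read.

    The ID is the concatenation of read bases aligned within the reference
    window ``[cut_site - flank, cut_site + flank)``: matches and mismatches
    contribute their read base, deletions contribute nothing (so the ID
    shortens), and insertions are included when they fall strictly inside the
    window.  A read that matches the reference exactly therefore yields the
    wildtype-ID, and differences outside the window do not change the ID.
    Reads that only partially cover the window yield the covered sub-window
    string; reads not overlapping the window at all yield ``None``.
    """
    win_lo, win_hi = cut_site - flank, cut_site + flank
    ref_pos = ref_start
    query_pos = 0
    out: list[str] = []
    overlapped = False
    for op, length in _normalize_cigar(cigar):
        if op in "M=X":
            lo = max(ref_pos, win_lo)
            hi = min(ref_pos + length, win_hi)
            if lo < hi:
                overlapped = True
                out.append(query[query_pos + (lo - ref_pos) : query_pos + (hi - ref_pos)])
            ref_pos += length
            query_pos += length
        elif op == "I":
            # insertion sits between ref_pos - 1 and ref_pos; keep it only
            # when strictly inside the window
            if win_lo < ref_pos < win_hi:
                overlapped = True
                out.append(query[query_pos : query_pos + length])
            query_pos += length
        elif op in "DN":
            if max(ref_pos, win_lo) < min(ref_pos + length, win_hi):
                overlapped = True  # deletion inside window: bases absent
            ref_pos += length
        elif op == "S":
            query_pos += length
        # H and P consume neither sequence
    if not overlapped:
        return None
    return "".join(out)


def extract_scar_id(
    sequence: str,
    ref: TargetReference,
    *,
    ref_start: int | None = None,
    cigar=None,
    flank: int = DEFAULT_FLANK,
) -> str | None:
    """Sequence-ID for a read, aligning it to the target reference if needed.

    When ``cigar``/``ref_start`` are not supplied the read is aligned with
    edlib (infix mode, so the read may start anywhere in the amplicon).
    """
    if cigar is None:
        import edlib

        aln = edlib.align(sequence, ref.sequence, mode="HW", task="path")
        ref_start = aln["locations"][0][0]
        cigar = aln["cigar"]
    elif ref_start is None:
        raise ValueError("ref_start is required when a CIGAR is supplied")
    return scar_id_from_alignment(sequence, cigar, ref_start, ref.cut_site, flank=flank)


def assign_scar_ids(
    reads: Iterable[ReadRecord],
    refs: Mapping[str, TargetReference],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Attach a sequence-ID to each read; reads not covering the window are skipped."""
    rows = []
    for read in reads:
        seq_id = extract_scar_id(read.sequence, refs[read.target], flank=flank)
        if seq_id is None:
            logger.warning("read in cell %s does not cover the %s window; skipped", read.cell, read.target)
            continue
        rows.append((read.cell, read.target, read.umi, seq_id))
    return pd.DataFrame(rows, columns=["cell", "target", "umi", "seq_id"])


def collapse_to_umis(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse reads with sequence-IDs into a ScarTable of UMI counts.

    Input columns: ``cell, target, umi, seq_id``.  A UMI observed with several
    sequence-IDs on one target is credited to its majority ID (ties to the
    lexicographically smallest).  Output columns:
    ``cell, target, seq_id, umi_count``.
    """
    if reads.empty:
        return pd.DataFrame(columns=["cell", "target", "seq_id", "umi_count"])
    counts = (
        reads.groupby(["cell", "target", "umi", "seq_id"], sort=False)
        .size()
        .reset_index(name="n_reads")
    )
    counts = counts.sort_values(
        ["cell", "target", "umi", "n_reads", "seq_id"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    majority = counts.drop_duplicates(["cell", "target", "umi"])
    table = (
        majority.groupby(["cell", "target", "seq_id"], sort=True)
        .size()
        .reset_index(name="umi_count")
    )
    return table


def filter_alleles(
    table: pd.DataFrame,
    top_fraction: float = 0.8,
    max_alleles: int = 2,
    max_flagged_targets: int = 1,
) -> AlleleTable:
    """Reduce a ScarTable to a diploid AlleleTable.

    Per (cell, target), sequence-IDs are sorted by UMI count (descending, ties
    lexicographic) and the minimal prefix whose cumulative count reaches
    ``top_fraction`` of the total is taken.  If that prefix holds more than
    ``max_alleles`` sequences the target is flagged for the cell and nothing
    is retained there; a cell with more than ``max_flagged_targets`` flagged
    targets is removed entirely as a putative doublet.
    """
    empty = pd.DataFrame(columns=["cell", "target", "seq_id", "umi_count"])
    if table.empty:
        return AlleleTable(retained=empty, flagged=pd.DataFrame(columns=["cell", "target"]))

    df = table.sort_values(
        ["cell", "target", "umi_count", "seq_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    grp = df.groupby(["cell", "target"], sort=False)
    total = grp["umi_count"].transform("sum")
    cum = grp["umi_count"].cumsum()
    # a row belongs to the minimal prefix iff the cumulative count *before* it
    # has not yet reached the threshold
    in_prefix = (cum - df["umi_count"]) < top_fraction * total - _FRACTION_EPS
    prefix = df[in_prefix]

    sizes = prefix.groupby(["cell", "target"], sort=False).size()
    flagged_pairs = sizes[sizes > max_alleles].index
    flagged = pd.DataFrame(flagged_pairs.tolist(), columns=["cell", "target"])

    flags_per_cell = flagged.groupby("cell").size() if not flagged.empty else pd.Series(dtype=int)
    doublets = sorted(flags_per_cell[flags_per_cell > max_flagged_targets].index)

    keep = prefix.merge(flagged, on=["cell", "target"], how="left", indicator=True)
    keep = keep[keep["_merge"] == "left_only"].drop(columns="_merge")
    keep = keep[~keep["cell"].isin(doublets)].reset_index(drop=True)
    return AlleleTable(retained=keep, flagged=flagged, doublets=doublets)


def filter_reads(
    reads: Iterable[ReadRecord],
    valid_barcodes: set[str],
    refs: Mapping[str, TargetReference],
    top_fraction: float = 0.8,
    max_alleles: int = 2,
    max_flagged_targets: int = 1,
    flank: int = DEFAULT_FLANK,
) -> AlleleTable:
    """Full read-level path: barcode/primer filtering, ID extraction, UMI collapse, diploid filter."""
    kept = preprocess_reads(reads, valid_barcodes, refs)
    with_ids = assign_scar_ids(kept, refs, flank=flank)
    table = collapse_to_umis(with_ids)
    return filter_alleles(
        table,
        top_fraction=top_fraction,
        max_alleles=max_alleles,
        max_flagged_targets=max_flagged_targets,
    )


def reads_from_tsv(path) -> Iterator[ReadRecord]:
    """Stream reads from a TSV with columns ``cell, target, umi, sequence``."""
    from .io import read_tsv

    df = read_tsv(path, dtype=str)
    for row in df.itertuples(index=False):
        yield ReadRecord(cell=row.cell, target=row.target, umi=row.umi, sequence=row.sequence)


def reads_from_sam(path) -> Iterator[ReadRecord]:
    """Stream reads from a SAM/BAM of target-aligned scar reads.

    The reference name is the target; cell barcode and UMI are taken from the
    ``CB``/``UB`` tags.  Unaligned records are skipped.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            try:
                cell = aln.get_tag("CB")
                umi = aln.get_tag("UB")
            except KeyError:
                logger.warning("alignment %s lacks CB/UB tags; skipped", aln.query_name)
                continue
            yield ReadRecord(
                cell=str(cell), target=aln.reference_name, umi=str(umi),
                sequence=aln.query_sequence or "",
            )
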