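"""5' end-motif frequency features from cfDNA fragment records.

Each fragment record carries the k-mer (default 4, hence 256 features) read
at its 5' end; one record contributes exactly one motif, so counting both
physical ends of a duplex fragment requires two records. Motifs containing
N are excluded from both numerator and denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import FeatureMatrix
from .synthetic import all_motifs

DEFAULT_K = 4


def motif_frequencies(
    fragments: pd.DataFrame, k: int = DEFAULT_K, min_fragments: int = 1
) -> pd.Series:
    """Frequency vector over the 4**k motifs (sums to 1 over usable fragments)."""
    if "motif5" not in fragments.columns:
        raise DataError("fragment table must have a motif5 column")
    col = fragments["motif5"]
    if isinstance(col.dtype, pd.CategoricalDtype):
        # validate the (small) category set, then count integer codes
        cats = col.cat.categories.astype(str)
        if (cats.str.len() != k).any():
            raise DataError(f"motif5 categories must have length {k}")
        code_counts = np.bincount(col.cat.codes[col.cat.codes >= 0],
                                  minlength=len(cats))
        raw = pd.Series(code_counts, index=cats)
    else:
        motifs = col.astype(str)
        bad_len = motifs.str.len() != k
        if bad_len.any():
            raise DataError(f"{int(bad_len.sum())} fragments have motif5 length != {k}")
        raw = motifs.value_counts()
    has_n = raw.index.str.contains("N", regex=False)
    usable_total = int(raw[~has_n].sum())
    if usable_total == 0:
        raise DataError("no usable fragments")
    if usable_total < min_fragments:
        raise DataError(
            f"only {usable_total} usable fragments; min_fragments={min_fragments}"
        )
    vocab = all_motifs(k)
    counts = raw.reindex(vocab, fill_value=0).rename(None)
    counts.index.name = None
    return counts / usable_total


def build_motif_matrix(
    fragments: pd.DataFrame,
    samples: pd.DataFrame,
    k: int = DEFAULT_K,
    min_fragments: int = 1,
) -> FeatureMatrix:
    """Samples x 4**k row-stochastic frequency matrix.

    Every sample in the sheet must have fragments; a sample with none (or
    none usable) aborts the build naming that sample.
    """
    known = set(samples["sample_id"])
    stray = set(fragments["sample_id"]) - known
    if stray:
        raise DataError(f"fragments reference unknown samples: {sorted(stray)[:5]}")
    rows = {}
    grouped = dict(tuple(fragments.groupby("sample_id", observed=True)))
    for sid in samples["sample_id"]:
        frag = grouped.get(sid)
        if frag is None or len(frag) == 0:
            raise DataError(f"sample {sid!r} has no fragments")
        try:
            rows[sid] = motif_frequencies(frag, k=k, min_fragments=min_fragments)
        except DataError as exc:
            raise DataError(f"sample {sid!r}: {exc}") from exc
    values = pd.DataFrame(
        {sid: rows[sid] for sid in samples["sample_id"]}
    ).T
    values.index.name = None
    return FeatureMatrix(values, "endmotif")


def motif_from_reference(
    fasta_path, chrom: str, start: int, end: int, strand: str, k: int = DEFAULT_K
) -> str:
    """Derive a fragment's 5' k-mer from a reference FASTA.

    For + strand reads the k bases at ``start``; for - strand, the k bases
    ending at ``end`` reverse-complemented (the 5' end of the minus-strand
    synthesis product).
    """
    from Bio import SeqIO

    comp = str.maketrans("ACGTN", "TGCAN")
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id != chrom:
            continue
        seq = str(rec.seq).upper()
        if strand == "-":
            sub = seq[end - k:end]
            return sub.translate(comp)[::-1]
        return seq[start:start + k]
    raise DataError(f"chromosome {chrom!r} not in reference")
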