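"""Genomic input handling: mutations, copy-number calls and the feature tensor.

Somatic mutations arrive either as MAF-like records or as a pre-aggregated
gene x sample count matrix; copy number arrives as GISTIC-style thresholded
integer calls in [-2, 2].  Both are reduced to the three per-gene input
channels the model consumes: nonsynonymous-mutation presence (or count),
high amplification (call == +2) and deep deletion (call == -2).  Single-copy
gains and losses are deliberately dropped.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import normalize_gene

__all__ = [
    "GeneMutationMatrix",
    "CopyNumberCalls",
    "ProfileTensor",
    "CohortLabels",
    "DEFAULT_EXCLUDED_CLASSES",
    "KNOWN_VARIANT_CLASSES",
    "load_mutations",
    "load_cnv",
    "load_labels",
    "assemble_profiles",
]

#: Variant classes removed before aggregation (non-coding / synonymous).
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "RNA", "lincRNA"}
)

#: Classes we recognise; anything else is retained with a warning (fail-open).
KNOWN_VARIANT_CLASSES = DEFAULT_EXCLUDED_CLASSES | {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
    "Nonstop_Mutation",
    "5'Flank",
    "3'Flank",
    "IGR",
    "Targeted_Region",
}

CHANNELS = ("mut", "amp", "del")


@dataclass
class GeneMutationMatrix:
    """Per-(sample, gene) counts of retained nonsynonymous mutations."""

    samples: list
    genes: list
    counts: np.ndarray  # (n_samples, n_genes) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.genes)):
            raise ValueError("counts shape does not match samples x genes")
        if np.any(self.counts < 0):
            raise ValueError("mutation counts must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")


@dataclass
class CopyNumberCalls:
    """GISTIC-style thresholded calls plus derived amp/del indicators."""

    samples: list
    genes: list
    calls: np.ndarray  # (n_samples, n_genes) ints in [-2, 2]

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        bad = ~np.isin(self.calls, [-2, -1, 0, 1, 2])
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"copy-number call out of range at sample {self.samples[i]!r}, "
                f"gene {self.genes[j]!r}: {self.calls[i, j]}"
            )

    @property
    def amplification(self):
        """1 iff high gain (call == +2); single-copy gains map to 0."""
        return (self.calls == 2).astype(np.int8)

    @property
    def deletion(self):
        """1 iff deep deletion (call == -2); single-copy losses map to 0."""
        return (self.calls == -2).astype(np.int8)


@dataclass
class ProfileTensor:
    """samples x genes x 3 feature array (mutation, amplification, deletion).

    Gene order matches the network's gene layer; ``flatten()`` produces the
    model input with the per-gene channel triples contiguous, aligned with
    the feature-layer node ordering ``<GENE>_mut, <GENE>_amp, <GENE>_del``.
    """

    samples: list
    genes: list
    values: np.ndarray  # (n_samples, n_genes, 3)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), len(self.genes), 3):
            raise ValueError("tensor shape does not match samples x genes x 3")
        amp, dele = self.values[:, :, 1], self.values[:, :, 2]
        if np.any((amp == 1) & (dele == 1)):
            raise ValueError("amplification and deletion cannot co-occur")

    @property
    def n_samples(self):
        return len(self.samples)

    def flatten(self):
        return self.values.reshape(self.n_samples, -1)

    def feature_names(self):
        return [f"{g}_{ch}" for g in self.genes for ch in CHANNELS]

    def subset(self, idx):
        idx = np.asarray(idx)
        return ProfileTensor(
            samples=[self.samples[i] for i in idx],
            genes=list(self.genes),
            values=self.values[idx],
        )


@dataclass
class CohortLabels:
    """Binary disease-state labels (0 = primary, 1 = metastatic/resistant)."""

    labels: dict = field(default_factory=dict)  # sample_id -> 0/1

    def __post_init__(self):
        for s, y in self.labels.items():
            if y not in (0, 1):
                raise ValueError(f"label for {s!r} must be 0 or 1, got {y!r}")

    @property
    def N(self):
        return len(self.labels)

    def vector(self, samples):
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return np.array([self.labels[s] for s in samples], dtype=np.int64)


# ---------------------------------------------------------------------------
# loading


def _read_table(source, **kw):
    if isinstance(source, (str, os.PathLike)) and str(source).endswith(".gz"):
        with gzip.open(source, "rt") as fh:
            return pd.read_csv(fh, **kw)
    try:
        return pd.read_csv(source, **kw)
    except Exception:
        # delimiter sniffing (sep=None) fails on very short inputs: fall
        # back to comma, the documented default dialect
        if kw.get("sep", "") is None and hasattr(source, "seek"):
            source.seek(0)
            kw = {k: v for k, v in kw.items() if k not in ("sep", "engine")}
            return pd.read_csv(source, **kw)
        raise


def load_mutations(source, excluded_classes=DEFAULT_EXCLUDED_CLASSES, dialect=None):
    """Load somatic mutations and aggregate retained records per (sample, gene).

    Parameters
    ----------
    source : path or file-like or DataFrame
        Either a MAF-like table with columns ``Hugo_Symbol``,
        ``Tumor_Sample_Barcode`` and ``Variant_Classification``, or a numeric
        gene x sample count matrix (genes as rows, header of sample IDs).
    excluded_classes : set of str
        Variant classes dropped before aggregation.  Default: silent,
        intronic, UTR, RNA and lincRNA records.
    dialect : {"maf", "matrix", None}
        Force the input interpretation; ``None`` auto-detects from columns.

    Notes
    -----
    Unknown ``Variant_Classification`` strings are *retained* with a warning,
    so unusual annotation dialects fail open rather than silently losing
    coding mutations.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = _read_table(source, sep=None, engine="python")

    maf_cols = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    is_maf = maf_cols.issubset(df.columns) if dialect is None else dialect == "maf"

    if is_maf:
        missing = maf_cols - set(df.columns)
        if missing:
            raise ValueError(f"MAF input missing required columns: {sorted(missing)}")
        excluded = frozenset(excluded_classes)
        if len(df):
            unknown = set(df["Variant_Classification"]) - KNOWN_VARIANT_CLASSES - excluded
            if unknown:
                warnings.warn(
                    f"unknown Variant_Classification values retained: {sorted(unknown)}",
                    stacklevel=2,
                )
        keep = df[~df["Variant_Classification"].isin(excluded)]
        samples = sorted(set(df["Tumor_Sample_Barcode"].astype(str)))
        genes = sorted({normalize_gene(g) for g in df["Hugo_Symbol"]})
        counts = np.zeros((len(samples), len(genes)), dtype=np.int64)
        si = {s: i for i, s in enumerate(samples)}
        gi = {g: j for j, g in enumerate(genes)}
        for s, g in zip(keep["Tumor_Sample_Barcode"].astype(str), keep["Hugo_Symbol"]):
            counts[si[s], gi[normalize_gene(g)]] += 1
        return GeneMutationMatrix(samples=samples, genes=genes, counts=counts)

    # matrix dialect: genes as rows, samples as columns
    if not isinstance(source, pd.DataFrame):
        df = _read_table(source, sep=None, engine="python", index_col=0)
    else:
        df = df.set_index(df.columns[0]) if df.index.dtype == np.int64 else df
    mat = df.to_numpy(dtype=np.float64)
    if np.any(mat < 0):
        raise ValueError("negative value in mutation count matrix")
    genes = [normalize_gene(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    order_g = np.argsort(genes)
    order_s = np.argsort(samples)
    return GeneMutationMatrix(
        samples=[samples[i] for i in order_s],
        genes=[genes[j] for j in order_g],
        counts=mat.T[np.ix_(order_s, order_g)].astype(np.int64),
    )


def load_cnv(source):
    """Load a gene x sample matrix of GISTIC thresholded calls.

    Values must be integers in [-2, 2]; anything else raises with the
    offending cell named.  Returns :class:`CopyNumberCalls`, whose
    ``amplification`` / ``deletion`` properties give the binary indicators
    (only +/-2 calls count).
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = _read_table(source, sep=None, engine="python", index_col=0)
    mat = df.to_numpy(dtype=np.float64)
    if not np.all(mat == np.round(mat)):
        i, j = np.argwhere(mat != np.round(mat))[0]
        raise ValueError(f"non-integer copy-number call at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    genes = [normalize_gene(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    order_g = np.argsort(genes)
    order_s = np.argsort(samples)
    return CopyNumberCalls(
        samples=[samples[i] for i in order_s],
        genes=[genes[j] for j in order_g],
        calls=mat.T[np.ix_(order_s, order_g)].astype(np.int64),
    )


def load_labels(source):
    """Load sample labels from a CSV with columns ``sample_id, response``."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = _read_table(source)
    if not {"sample_id", "response"}.issubset(df.columns):
        raise ValueError("labels file needs columns sample_id, response")
    return CohortLabels(
        labels={str(s): int(y) for s, y in zip(df["sample_id"], df["response"])}
    )


def assemble_profiles(mut, cnv, net, binarize_mutations=True):
    """Assemble the samples x genes x 3 input tensor for a compiled network.

    The sample set is the (sorted) intersection of the mutation and
    copy-number sources; the gene axis is exactly the network's gene layer,
    with genes missing from a source zero-filled.  With
    ``binarize_mutations`` (the default) the mutation channel is presence
    (count > 0) rather than the raw count.
    """
    samples = sorted(set(mut.samples) & set(cnv.samples))
    if not samples:
        raise ValueError("no samples shared between mutation and copy-number sources")
    genes = net.genes
    if not genes:
        raise ValueError("network has an empty gene layer")

    values = np.zeros((len(samples), len(genes), 3), dtype=np.float64)

    mi = {s: i for i, s in enumerate(mut.samples)}
    mg = {g: j for j, g in enumerate(mut.genes)}
    ci = {s: i for i, s in enumerate(cnv.samples)}
    cg = {g: j for j, g in enumerate(cnv.genes)}
    amp, dele = cnv.amplification, cnv.deletion

    for i, s in enumerate(samples):
        for j, g in enumerate(genes):
            if g in mg:
                c = mut.counts[mi[s], mg[g]]
                values[i, j, 0] = (c > 0) if binarize_mutations else c
            if g in cg:
                values[i, j, 1] = amp[ci[s], cg[g]]
                values[i, j, 2] = dele[ci[s], cg[g]]

    return ProfileTensor(samples=samples, genes=list(genes), values=values)


def write_profiles(tensor, outdir):
    """Write a ProfileTensor as three gene x sample CSVs (mut/amp/del)."""
    os.makedirs(outdir, exist_ok=True)
    for k, ch in enumerate(CHANNELS):
        pd.DataFrame(
            tensor.values[:, :, k].T, index=tensor.genes, columns=tensor.samples
        ).to_csv(os.path.join(outdir, f"profile_{ch}.csv"))


def read_profiles(outdir):
    """Inverse of :func:`write_profiles` (exact round trip)."""
    mats = []
    genes = samples = None
    for ch in CHANNELS:
        df = pd.read_csv(os.path.join(outdir, f"profile_{ch}.csv"), index_col=0)
        genes = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        mats.append(df.to_numpy(dtype=np.float64).T)
    values = np.stack(mats, axis=2)
    return ProfileTensor(samples=samples, genes=genes, values=values)
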