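"""Count-matrix aggregation, normalization and filtering.

Three conventions are implemented, one per analysis site:

* animal-level counts summed to tissue level, then aggregated to organ
  level by taking the maximum member-tissue count (so an organ's signal is
  its best tissue, not an average diluted across tissues);
* trimmed-mean-of-M-values (TMM) scaling against a reference sample,
  followed by a "seen at >= 10 normalized reads in at least one sample"
  retention filter;
* transcripts-per-million (TPM) scaling with zero imputation at 1.0 and
  integer ceiling.

Percentile computations use linear interpolation (NumPy default, R type 7)
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .organs import validate_organ_map


@dataclass
class AtlasCounts:
    """A miRNA x sample count matrix with animal/sex/tissue/organ metadata.

    ``counts``: DataFrame indexed by miRNA id, one column per sample.
    ``samples``: DataFrame indexed by sample id with columns
    ``animal``, ``sex``, ``tissue``, ``organ``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample sheet rows must align")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("miRNA ids must be unique")
        per_tissue = self.samples.groupby("tissue")["organ"].nunique()
        if (per_tissue > 1).any():
            bad = per_tissue[per_tissue > 1].index.tolist()
            raise ValueError(f"tissues map to more than one organ: {bad}")

    @property
    def mirnas(self) -> list[str]:
        return list(self.counts.index)

    def tissue_of(self) -> pd.Series:
        return self.samples["tissue"]

    def n_animals(self, tissue: str) -> int:
        return int((self.samples["tissue"] == tissue).sum())

    def organ_map(self) -> dict[str, str]:
        return dict(zip(self.samples["tissue"], self.samples["organ"]))

    # -- TSV round trip -----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write matrix plus a commented metadata header block."""
        with open(path, "w") as fh:
            for key in ("animal", "sex", "tissue", "organ"):
                vals = "\t".join(self.samples[key].astype(str))
                fh.write(f"#{key}\t{vals}\n")
            self.counts.rename_axis("mirna").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AtlasCounts":
        meta: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *vals = line[1:].rstrip("\n").split("\t")
                meta[key] = vals
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            counts = pd.read_csv(fh, sep="\t", index_col=0).rename_axis(None)
        keys = ("animal", "sex", "tissue", "organ")
        missing = [k for k in keys if k not in meta]
        if missing:
            raise ValueError(f"metadata header block missing rows: {missing}")
        samples = pd.DataFrame({k: meta[k] for k in keys}, index=counts.columns)
        samples.index.name = "sample"
        return cls(counts=counts, samples=samples)


def aggregate_tissue(atlas: AtlasCounts) -> pd.DataFrame:
    """Tissue-level counts: sum each miRNA over all animals per tissue."""
    tissues = atlas.samples["tissue"]
    if tissues.empty:
        raise ValueError("no samples to aggregate")
    out = atlas.counts.T.groupby(tissues).sum().T
    # preserve first-appearance tissue order
    order = list(dict.fromkeys(tissues))
    return out[order]


def aggregate_organ(tissue_matrix: pd.DataFrame, organ_map: dict[str, str]) -> pd.DataFrame:
    """Organ-level counts: the maximum of the member tissues' counts."""
    validate_organ_map(organ_map, list(tissue_matrix.columns))
    organs = pd.Series({t: organ_map[t] for t in tissue_matrix.columns})
    out = tissue_matrix.T.groupby(organs).max().T
    order = list(dict.fromkeys(organ_map[t] for t in tissue_matrix.columns))
    return out[order]


def tmm_factors(
    matrix: pd.DataFrame,
    reference: str | None = None,
    *,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors against a reference sample.

    M-values are per-gene log2 ratios of raw counts sample/reference and
    A-values their log2 geometric-mean abundance; genes zero in either
    sample are excluded, the most extreme ``logratio_trim`` of M and
    ``abundance_trim`` of A are trimmed from both tails, and the factor is
    2**(precision-weighted mean of the surviving M).  The reported factor
    therefore captures total depth and composition relative to the
    reference (a library scaled by c gets factor c); the reference's own
    factor is 1.
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one sample")
    lib = matrix.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero samples have undefined TMM factors: {bad}")
    if reference is None:
        # edgeR's heuristic: sample whose upper quartile is closest to the mean
        uq = matrix.apply(lambda c: np.percentile(c / c.sum(), 75), axis=0)
        reference = (uq - uq.mean()).abs().idxmin()
    ref = matrix[reference].to_numpy(dtype=float)
    nref = ref.sum()
    factors = {}
    for sample in matrix.columns:
        obs = matrix[sample].to_numpy(dtype=float)
        if sample == reference:
            factors[sample] = 1.0
            continue
        nobs = obs.sum()
        ok = (obs > 0) & (ref > 0)
        y, r = obs[ok], ref[ok]
        m = np.log2(y) - np.log2(r)
        a = 0.5 * (np.log2(y / nobs) + np.log2(r / nref))
        # delta-method weight: inverse asymptotic variance of M
        w = (nobs - y) / (nobs * y) + (nref - r) / (nref * r)
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            keep = np.ones_like(m, dtype=bool)
        with np.errstate(divide="ignore"):
            wk = np.where(w[keep] > 0, 1.0 / np.maximum(w[keep], 1e-300), 0.0)
        factors[sample] = float(2 ** (np.sum(wk * m[keep]) / np.sum(wk)))
    return pd.Series(factors, name="tmm_factor")


def tmm_normalize(
    matrix: pd.DataFrame,
    reference: str | None = None,
    *,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM factors and the normalized matrix (counts divided per-sample).

    Normalized values stay on the reference sample's count scale, which is
    what the downstream <10-read retention filter expects.
    """
    factors = tmm_factors(
        matrix, reference, logratio_trim=logratio_trim, abundance_trim=abundance_trim
    )
    return factors, matrix / factors


def filter_low_counts(matrix: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Retain miRNAs with >= threshold (normalized) reads in >= 1 sample."""
    keep = (matrix >= threshold).any(axis=1)
    return matrix.loc[keep]


def tpm_normalize(
    matrix: pd.DataFrame, *, impute_zero: bool = True, ceil: bool = True
) -> pd.DataFrame:
    """Transcripts-per-million scaling per sample.

    Zeros are imputed with 1.0 before scaling (so every miRNA keeps a
    nonzero floor), each column is scaled to counts-per-million of its
    post-imputation total, and values are ceiled to integers for count
    models downstream.  Without imputation/ceiling, columns sum to 1e6.
    """
    mat = matrix.astype(float)
    if impute_zero:
        mat = mat.where(mat > 0, 1.0)
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero sample totals: {bad}")
    tpm = mat / totals * 1e6
    if ceil:
        tpm = np.ceil(tpm).astype(int)
    return tpm
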