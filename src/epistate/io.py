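"""Readers and writers for the plain-text genomics formats the pipeline uses.

bedGraph and BED are 0-based half-open; GTF is 1-based closed; per-CpG
methylation tables use 1-based positions.  Cell matrices round-trip through
MatrixMarket (MTX) plus row/column name files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_state import GeneModel
from .segmentation import GenomeBins, SegmentationModel, StateTrack


def write_bedgraph(path, bins: GenomeBins, values) -> None:
    starts = bins.starts()
    df = pd.DataFrame({"chrom": bins.chrom, "start": starts,
                       "end": starts + bins.bin_size, "value": values})
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end", "value"])


def bedgraph_to_bins(df: pd.DataFrame, bins: GenomeBins) -> np.ndarray:
    """Per-bin values from a bedGraph that tiles the bins exactly."""
    out = np.zeros(bins.n_bins)
    sel = df["chrom"] == bins.chrom
    idx = df.loc[sel, "start"].to_numpy() // bins.bin_size
    out[idx] = df.loc[sel, "value"].to_numpy()
    return out


def write_cpg_table(path, cpg: pd.DataFrame) -> None:
    cpg.to_csv(path, sep="\t", index=False)


def read_cpg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gtf(path, genes: list[GeneModel], source: str = "epistate") -> None:
    """1-based closed coordinates; attributes include gene_biotype and the
    "basic" tag."""
    with open(path, "w") as fh:
        for g in genes:
            tag = ' tag "basic";' if g.basic else ""
            attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                     f'gene_biotype "{g.biotype}";{tag}')
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def write_peaks_bed(path, peaks: pd.DataFrame) -> None:
    peaks[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                            index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_segmentation_bed(path, track: StateTrack) -> None:
    """Segmentation as BED9: consecutive same-state bins are merged; the
    score is 1000 x the mean max-posterior over the segment."""
    states = track.states
    change = np.flatnonzero(np.diff(states)) + 1
    seg_starts = np.concatenate([[0], change])
    seg_ends = np.concatenate([change, [len(states)]])
    labels = track.labels or {}
    bsz = track.bins.bin_size
    with open(path, "w") as fh:
        for a, b in zip(seg_starts, seg_ends):
            s = int(states[a])
            name = labels.get(s, f"state_{s}")
            if track.posteriors is not None:
                score = int(round(track.posteriors[a:b].max(axis=1).mean() * 1000))
            else:
                score = 1000
            start, end = a * bsz, b * bsz
            fh.write(f"{track.bins.chrom}\t{start}\t{end}\t{name}\t{score}\t.\t"
                     f"{start}\t{end}\t0,0,0\n")


def write_model_json(path, model: SegmentationModel, channel_names=None) -> None:
    payload = {
        "pi": model.pi.tolist(),
        "A": model.A.tolist(),
        "means": model.means.tolist(),
        "dispersion": [None if np.isinf(d) else float(d)
                       for d in model.dispersion],
        "emission": model.emission,
        "channels": list(channel_names) if channel_names else None,
        "loglik": model.loglik_history[-1] if model.loglik_history else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_json(path) -> SegmentationModel:
    payload = json.loads(Path(path).read_text())
    disp = np.array([np.inf if d is None else d for d in payload["dispersion"]])
    return SegmentationModel(pi=np.array(payload["pi"]),
                             A=np.array(payload["A"]),
                             means=np.array(payload["means"]),
                             dispersion=disp, emission=payload["emission"])


def write_cell_matrix(outdir, adata) -> None:
    """AnnData counts as MTX (genes stored column-wise) + name files + obs TSV."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    spio.mmwrite(str(outdir / "matrix.mtx"), csr_matrix(np.asarray(X)))
    (outdir / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")
    (outdir / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    adata.obs.to_csv(outdir / "obs.tsv", sep="\t")


def read_cell_matrix(indir):
    import anndata as ad
    from scipy import io as spio

    indir = Path(indir)
    X = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense())
    cells = (indir / "cells.txt").read_text().splitlines()
    genes = (indir / "genes.txt").read_text().splitlines()
    obs = pd.DataFrame(index=cells)
    if (indir / "obs.tsv").exists():
        obs = pd.read_csv(indir / "obs.tsv", sep="\t", index_col=0)
    return ad.AnnData(X=X.astype(np.int64), obs=obs,
                      var=pd.DataFrame(index=genes))


def write_cohort(path, cohort) -> None:
    df = cohort.expression.copy()
    df.insert(0, "trait", cohort.trait)
    df.to_csv(path, sep="\t")


def read_cohort(path, gene_states: pd.Series | None = None):
    from .state_integration import CohortExpression

    df = pd.read_csv(path, sep="\t", index_col=0)
    trait = df.pop("trait")
    return CohortExpression(expression=df, trait=trait, gene_states=gene_states)
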