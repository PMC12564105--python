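"""Reference-based labeling of ICA components and dataset assembly.

Each ICA component of each 10-s epoch is scored against the ocular (MOG)
and cardiac (MCG) magnetic reference signals with the randomized
dependence coefficient.  Per epoch and per reference, the single most
correlated component above a threshold delta becomes the artifact sample;
components with both scores below a stricter threshold lambda become
non-artifact samples; everything in between is discarded as ambiguous.
Labeled waveforms are pooled across epochs into a class-balanced dataset
(blink : cardiac : non-artifact = 1 : 1 : 4), doubled by sign inversion
(ICA component polarity is arbitrary), and split 4:1 for training/testing
with sign-inverted twins always co-partitioned.

Class coding: 0 = cardiac, 1 = blink, 2 = non-artifact; -1 marks
unlabeled (ambiguous) components that never enter the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .preprocessing import ICADecomposition, bandpass_filter, ica_decompose, segment_epochs
from .rdc import RDCParams, rdc_against_references
from .recording import Recording

LABEL_CARDIAC = 0
LABEL_BLINK = 1
LABEL_NONE = 2
UNLABELED = -1


def score_components(
    decomposition: ICADecomposition,
    mog: np.ndarray,
    mcg: np.ndarray,
    params: RDCParams | None = None,
    epoch_id: int = 0,
) -> pd.DataFrame:
    """RDC of every component against both magnetic references.

    Returns one row per component with columns
    ``epoch_id, component_id, rdc_mog, rdc_mcg``.
    """
    params = params or RDCParams()
    n = decomposition.sources.shape[1]
    if len(mog) != n or len(mcg) != n:
        raise ValueError("references must cover the same window as the sources")
    scores = rdc_against_references(decomposition.sources, (mog, mcg), params)
    return pd.DataFrame(
        {
            "epoch_id": epoch_id,
            "component_id": np.arange(decomposition.n_components),
            "rdc_mog": scores[:, 0],
            "rdc_mcg": scores[:, 1],
        }
    )


def label_components(
    table: pd.DataFrame, delta: float = 0.3, lam: float = 0.2
) -> pd.DataFrame:
    """Threshold the score table into class labels, per epoch.

    Per epoch and reference, at most one component is labeled as that
    artifact: the one with the highest score, provided it exceeds
    ``delta``.  A component winning both references takes the class of its
    larger score (ties go to cardiac, whose morphology is the more
    stereotyped).  Components with both scores below ``lam`` are labeled
    non-artifact; the rest stay unlabeled (-1) and are excluded.
    """
    if delta <= lam:
        raise ValueError("delta must exceed lambda")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    out = table.copy()
    out["label"] = UNLABELED
    for _, grp in out.groupby("epoch_id"):
        blink_winner = cardiac_winner = None
        above_mog = grp[grp["rdc_mog"] > delta]
        if len(above_mog):
            blink_winner = above_mog["rdc_mog"].idxmax()
        above_mcg = grp[grp["rdc_mcg"] > delta]
        if len(above_mcg):
            cardiac_winner = above_mcg["rdc_mcg"].idxmax()
        if blink_winner is not None and blink_winner == cardiac_winner:
            row = out.loc[blink_winner]
            if row["rdc_mog"] > row["rdc_mcg"]:
                cardiac_winner = None
            else:
                blink_winner = None  # ties -> cardiac
        if blink_winner is not None:
            out.loc[blink_winner, "label"] = LABEL_BLINK
        if cardiac_winner is not None:
            out.loc[cardiac_winner, "label"] = LABEL_CARDIAC
        none_mask = (grp["rdc_mog"] < lam) & (grp["rdc_mcg"] < lam)
        none_idx = [
            i
            for i in grp.index[none_mask]
            if i not in (blink_winner, cardiac_winner)
        ]
        out.loc[none_idx, "label"] = LABEL_NONE
    return out


@dataclass
class ArtifactDataset:
    """Labeled component waveforms with provenance.

    ``provenance`` carries one ``(session, epoch, component, inverted)``
    tuple per sample; ``group_ids`` ties each sample to its sign-inversion
    twin so dataset splits never separate them.
    """

    waveforms: np.ndarray  # (n_samples, n_points)
    labels: np.ndarray  # (n_samples,) in {0, 1, 2}
    provenance: list = field(default_factory=list)
    group_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.group_ids is None:
            self.group_ids = np.arange(len(self.labels))
        else:
            self.group_ids = np.asarray(self.group_ids, dtype=np.int64)

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def class_counts(self) -> dict:
        return {
            int(c): int((self.labels == c).sum())
            for c in (LABEL_CARDIAC, LABEL_BLINK, LABEL_NONE)
        }

    def subset(self, idx: np.ndarray) -> "ArtifactDataset":
        return ArtifactDataset(
            self.waveforms[idx],
            self.labels[idx],
            [self.provenance[i] for i in idx] if self.provenance else [],
            self.group_ids[idx],
        )

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("waveforms", data=self.waveforms)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("group_ids", data=self.group_ids)
            if self.provenance:
                prov = np.array(
                    [str(p) for p in self.provenance], dtype=h5py.string_dtype()
                )
                f.create_dataset("provenance", data=prov)

    @classmethod
    def from_hdf5(cls, path) -> "ArtifactDataset":
        with h5py.File(path, "r") as f:
            prov = (
                [p.decode() for p in f["provenance"][()]]
                if "provenance" in f
                else []
            )
            return cls(
                f["waveforms"][()], f["labels"][()], prov, f["group_ids"][()]
            )


def assemble_dataset(
    waveforms: np.ndarray,
    labels: np.ndarray,
    provenance: list | None = None,
    ratio: tuple[int, int, int] = (1, 1, 4),
    seed: int = 0,
) -> ArtifactDataset:
    """Balance labeled pools to blink : cardiac : non-artifact = 1 : 1 : 4.

    The artifact classes are subsampled (seeded, without replacement) to
    the size of the smaller one, and the non-artifact pool to four times
    that count.  Raises with the deficit if too few non-artifact samples
    exist.  Unlabeled (-1) rows are ignored.
    """
    labels = np.asarray(labels, dtype=np.int64)
    waveforms = np.asarray(waveforms, dtype=np.float64)
    provenance = provenance or [("", 0, i, False) for i in range(len(labels))]
    rng = np.random.default_rng(seed)
    pools = {c: np.flatnonzero(labels == c) for c in (LABEL_CARDIAC, LABEL_BLINK, LABEL_NONE)}
    for c, pool in pools.items():
        if pool.size == 0:
            raise ValueError(f"empty pool for class {c}")
    m = min(pools[LABEL_CARDIAC].size, pools[LABEL_BLINK].size)
    r_art, _, r_none = ratio[0], ratio[1], ratio[2]
    n_none = m * r_none // r_art
    if pools[LABEL_NONE].size < n_none:
        raise ValueError(
            f"insufficient non-artifact samples: need {n_none}, "
            f"have {pools[LABEL_NONE].size} "
            f"(deficit {n_none - pools[LABEL_NONE].size})"
        )
    keep = np.concatenate(
        [
            np.sort(rng.choice(pools[LABEL_CARDIAC], m, replace=False)),
            np.sort(rng.choice(pools[LABEL_BLINK], m, replace=False)),
            np.sort(rng.choice(pools[LABEL_NONE], n_none, replace=False)),
        ]
    )
    return ArtifactDataset(
        waveforms[keep],
        labels[keep],
        [provenance[i] for i in keep],
        np.arange(keep.size),
    )


def augment_invert(dataset: ArtifactDataset) -> ArtifactDataset:
    """Append the sign-inverted twin of every sample (labels unchanged).

    ICA fixes component scale but not polarity, so ``-waveform`` is an
    equally valid realization of the same class; the twin keeps its
    original's group id so splits can co-partition them.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    prov_inv = [(*p[:3], True) for p in dataset.provenance]
    return ArtifactDataset(
        np.vstack([dataset.waveforms, -dataset.waveforms]),
        np.concatenate([dataset.labels, dataset.labels]),
        dataset.provenance + prov_inv,
        np.concatenate([dataset.group_ids, dataset.group_ids]),
    )


def split_dataset(
    dataset: ArtifactDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[ArtifactDataset, ArtifactDataset]:
    """Stratified train/test split that never separates inversion twins.

    Splitting operates on twin groups within each class, so a waveform and
    its sign-flip always land in the same partition; per class the test
    share is ``round(n_groups * test_fraction)`` groups.
    """
    if len(dataset) < 5:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(seed)
    test_idx = []
    train_idx = []
    for c in (LABEL_CARDIAC, LABEL_BLINK, LABEL_NONE):
        cls_mask = dataset.labels == c
        groups = np.unique(dataset.group_ids[cls_mask])
        perm = rng.permutation(groups)
        n_test = int(round(groups.size * test_fraction))
        test_groups = set(perm[:n_test].tolist())
        for i in np.flatnonzero(cls_mask):
            (test_idx if int(dataset.group_ids[i]) in test_groups else train_idx).append(i)
    return (
        dataset.subset(np.array(sorted(train_idx), dtype=int)),
        dataset.subset(np.array(sorted(test_idx), dtype=int)),
    )


def shorten_waveforms(dataset: ArtifactDataset, target_length: int) -> ArtifactDataset:
    """Stride-subsample every waveform down to ``target_length`` points.

    Valid for band-limited components (the pipeline filters to 1.5-40 Hz,
    far below the Nyquist rate of the subsampled series); the length must
    divide the original length.
    """
    n_points = dataset.waveforms.shape[1]
    if n_points % target_length:
        raise ValueError(
            f"target_length {target_length} must divide waveform length {n_points}"
        )
    step = n_points // target_length
    return ArtifactDataset(
        dataset.waveforms[:, ::step].copy(),
        dataset.labels.copy(),
        list(dataset.provenance),
        dataset.group_ids.copy(),
    )


def collect_labeled_components(
    recording: Recording,
    session_id: str = "s0",
    rdc_params: RDCParams | None = None,
    delta: float = 0.3,
    lam: float = 0.2,
    low: float = 1.5,
    high: float = 40.0,
    epoch_seconds: float = 10.0,
    n_components: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list, pd.DataFrame]:
    """Run filter -> epoch -> per-epoch ICA -> RDC scoring -> labeling.

    Returns the stacked component waveforms, their labels (including -1
    for ambiguous components), provenance tuples, and the full score
    table.  This is the session-level feeder for :func:`assemble_dataset`.
    """
    rdc_params = rdc_params or RDCParams()
    filtered = bandpass_filter(recording, low, high)
    epochs = segment_epochs(filtered, epoch_seconds)
    meg_rows = recording.meg_indices
    mog_row, mcg_row = recording.mog_index, recording.mcg_index

    waveforms, labels, provenance, tables = [], [], [], []
    for e in range(len(epochs)):
        epoch = epochs.epochs[e]
        dec = ica_decompose(epoch[meg_rows], n_components, seed=seed + 1000 * e)
        table = score_components(
            dec, epoch[mog_row], epoch[mcg_row], rdc_params, epoch_id=e
        )
        labeled = label_components(table, delta, lam)
        tables.append(labeled)
        for _, row in labeled.iterrows():
            c = int(row["component_id"])
            waveforms.append(dec.sources[c])
            labels.append(int(row["label"]))
            provenance.append((session_id, e, c, False))
    return (
        np.array(waveforms),
        np.array(labels, dtype=np.int64),
        provenance,
        pd.concat(tables, ignore_index=True),
    )
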