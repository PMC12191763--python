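"""Container and checkpoint I/O.

Embedding datasets are stored padded with a lengths index, in HDF5
(primary) or NPZ (fallback) under a shared key schema:

    embeddings : (N, Lmax, D) float
    lengths    : (N,) int
    labels     : (N, Lmax) int, optional
    coords     : (N, Lmax, 3) float, optional

Checkpoints bundle model weights, the architecture config and the channel
normalization stats into a single NPZ, so a compressed file is
self-describing.  All writes are atomic (write to a temp file in the same
directory, then rename).  Token exports are whitespace-separated integers,
one protein per line; labels can be exported as FASTA over the 21-letter
alphabet (20 amino acids + 'X').
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np

from .hourglass import HourglassAutoencoder, HourglassConfig
from .norm import ChannelStats
from .synthetic import LABEL_ALPHABET, SyntheticConfig, SyntheticDataset, pad_and_stack

__all__ = [
    "write_container",
    "read_container",
    "save_checkpoint",
    "load_checkpoint",
    "write_labels_fasta",
    "write_tokens",
    "write_pdb",
    "read_pdb",
    "adapter_stream",
]

EXPECTED_CHANNELS = 1024


class ContainerError(ValueError):
    pass


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_container(path, dataset: SyntheticDataset) -> None:
    """Write a ragged dataset as a padded container (HDF5 or NPZ by suffix)."""
    path = Path(path)
    emb, mask, labels = pad_and_stack(dataset)
    lengths = dataset.lengths
    arrays = {"embeddings": emb, "lengths": lengths, "labels": labels}
    if dataset.coords is not None:
        lmax = emb.shape[1]
        coords = np.zeros((len(dataset), lmax, 3))
        for i, c in enumerate(dataset.coords):
            coords[i, : c.shape[0]] = c
        arrays["coords"] = coords

    if path.suffix in (".h5", ".hdf5"):
        def writer(tmp):
            with h5py.File(tmp, "w") as fh:
                for key, arr in arrays.items():
                    fh.create_dataset(key, data=arr)
                fh.attrs["seed"] = dataset.config.seed
    elif path.suffix == ".npz":
        def writer(tmp):
            np.savez(tmp, **arrays)
    else:
        raise ContainerError(f"unsupported container suffix {path.suffix!r}")
    _atomic_write(path, writer)


def _ragged_from_arrays(arrays: dict) -> SyntheticDataset:
    for key in ("embeddings", "lengths"):
        if key not in arrays:
            raise ContainerError(f"container is missing required key {key!r}")
    emb = np.asarray(arrays["embeddings"])
    lengths = np.asarray(arrays["lengths"]).astype(int)
    if emb.ndim != 3:
        raise ContainerError(f"'embeddings' must be (N, Lmax, D), got shape {emb.shape}")
    if lengths.shape[0] != emb.shape[0]:
        raise ContainerError("lengths count does not match embeddings")
    if lengths.max(initial=0) > emb.shape[1]:
        raise ContainerError(
            f"a length ({lengths.max()}) exceeds the padded dimension ({emb.shape[1]})"
        )
    labels_arr = arrays.get("labels")
    coords_arr = arrays.get("coords")
    embeddings, masks, labels, coords = [], [], [], []
    for i, li in enumerate(lengths):
        embeddings.append(emb[i, :li].copy())
        masks.append(np.ones(li, dtype=np.int8))
        if labels_arr is not None:
            labels.append(np.asarray(labels_arr)[i, :li].astype(np.int64))
        else:
            labels.append(np.zeros(li, dtype=np.int64))
        if coords_arr is not None:
            coords.append(np.asarray(coords_arr)[i, :li].copy())
    cfg = SyntheticConfig(n_samples=len(lengths),
                          length_range=(max(4, int(lengths.min())), int(lengths.max())),
                          n_channels=emb.shape[2])
    return SyntheticDataset(embeddings=embeddings, masks=masks, labels=labels,
                            coords=coords if coords_arr is not None else None,
                            config=cfg)


def read_container(path) -> SyntheticDataset:
    """Read a padded container back into a ragged dataset, honoring lengths."""
    path = Path(path)
    if not path.exists():
        raise ContainerError(f"no such container: {path}")
    try:
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as fh:
                arrays = {k: fh[k][...] for k in fh.keys()}
        elif path.suffix == ".npz":
            with np.load(path) as npz:
                arrays = {k: npz[k] for k in npz.files}
        else:
            raise ContainerError(f"unsupported container suffix {path.suffix!r}")
    except (OSError, ValueError) as exc:
        raise ContainerError(f"cannot parse container {path}: {exc}") from exc
    return _ragged_from_arrays(arrays)


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(path, trained) -> None:
    """Single-file archive: weights + HourglassConfig + ChannelStats."""
    path = Path(path)
    cfg_json = json.dumps(dataclasses.asdict(trained.config))
    tcfg_json = json.dumps(dataclasses.asdict(trained.train_config))
    arrays = {f"param::{k}": v for k, v in trained.model.state_dict().items()}
    arrays["config_json"] = np.bytes_(cfg_json.encode())
    arrays["train_config_json"] = np.bytes_(tcfg_json.encode())
    arrays["stats_x_min"] = trained.stats.x_min
    arrays["stats_x_max"] = trained.stats.x_max
    arrays["stats_bounds"] = np.array([trained.stats.c_min, trained.stats.c_max])
    arrays["stats_n"] = np.array([trained.stats.n_samples_used])
    arrays["loss_trace"] = np.array(trained.loss_trace)
    arrays["lr_trace"] = np.array(trained.lr_trace)

    def writer(tmp):
        with open(tmp, "wb") as fh:
            np.savez(fh, **arrays)

    _atomic_write(path, writer)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; rebuilds the model and stats."""
    from .train import TrainConfig, TrainedCompressor

    with np.load(path, allow_pickle=False) as npz:
        cfg_dict = json.loads(bytes(npz["config_json"]).decode())
        tcfg_dict = json.loads(bytes(npz["train_config_json"]).decode())
        if cfg_dict.get("fsq_levels") is not None:
            cfg_dict["fsq_levels"] = tuple(cfg_dict["fsq_levels"])
        cfg = HourglassConfig(**cfg_dict)
        model = HourglassAutoencoder(cfg)
        state = {k[len("param::"):]: npz[k] for k in npz.files if k.startswith("param::")}
        model.load_state_dict(state)
        stats = ChannelStats(
            x_min=npz["stats_x_min"], x_max=npz["stats_x_max"],
            c_min=float(npz["stats_bounds"][0]), c_max=float(npz["stats_bounds"][1]),
            n_samples_used=int(npz["stats_n"][0]),
        )
        return TrainedCompressor(
            model=model, config=cfg, stats=stats,
            train_config=TrainConfig(**tcfg_dict),
            loss_trace=npz["loss_trace"].tolist(),
            lr_trace=npz["lr_trace"].tolist(),
        )


# ------------------------------------------------------------------- exports

def write_labels_fasta(path, dataset: SyntheticDataset) -> None:
    """Export per-residue labels as FASTA over the 21-letter alphabet."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq("".join(LABEL_ALPHABET[t] for t in lab)),
                  id=f"sample_{i}", description="")
        for i, lab in enumerate(dataset.labels)
    ]

    def writer(tmp):
        with open(tmp, "w") as fh:
            seqio_write(records, fh, "fasta")

    _atomic_write(Path(path), writer)


def write_tokens(path, token_lists) -> None:
    """Whitespace-separated integer tokens, one protein per line."""
    def writer(tmp):
        with open(tmp, "w") as fh:
            for toks in token_lists:
                idx = toks.indices if hasattr(toks, "indices") else np.asarray(toks)
                if getattr(toks, "mask", None) is not None:
                    idx = idx[np.asarray(toks.mask).astype(bool)]
                fh.write(" ".join(str(int(t)) for t in np.ravel(idx)) + "\n")

    _atomic_write(Path(path), writer)


def write_pdb(path, coords: np.ndarray, chain: str = "A") -> None:
    """Write a CA-only single-chain PDB for a toy backbone."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id = np.full(n, chain)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")

    def writer(tmp):
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(tmp)

    _atomic_write(Path(path), writer)


def read_pdb(path, atom_name: str | None = "CA") -> np.ndarray:
    """Read coordinates from a single-model PDB (optionally one atom type)."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1)
    if atom_name is not None:
        atoms = atoms[atoms.atom_name == atom_name]
    return np.asarray(atoms.coord, dtype=np.float64)


# ------------------------------------------------------------------- adapter

def adapter_stream(provider, n_channels: int = EXPECTED_CHANNELS):
    """Validating seam for external latent providers.

    ``provider`` is any iterable yielding ``(embedding (L, D), mask (L,))``
    pairs — e.g. real folding-model latents.  Downstream code treats the
    stream identically to synthetic data; items with the wrong channel
    count are rejected.
    """
    for i, (emb, mask) in enumerate(provider):
        emb = np.asarray(emb, dtype=np.float64)
        mask = np.asarray(mask)
        if emb.ndim != 2 or emb.shape[1] != n_channels:
            raise ValueError(
                f"provider item {i}: expected (L, {n_channels}) embedding, got {emb.shape}"
            )
        if mask.shape != (emb.shape[0],):
            raise ValueError(f"provider item {i}: mask must be length {emb.shape[0]}")
        yield emb, mask
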