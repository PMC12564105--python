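"""Multichannel OPM-MEG recording container and HDF5 persistence.

A :class:`Recording` holds a channels-by-samples matrix together with the
sampling rate and one role tag per channel.  Roles distinguish the MEG
sensor array from the two magnetic artifact-reference sensors (ocular MOG
and cardiac MCG) and the stimulus trigger line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

#: Valid channel roles.
ROLE_MEG = "MEG"
ROLE_MOG = "MOG_REF"
ROLE_MCG = "MCG_REF"
ROLE_TRIGGER = "TRIGGER"
ALL_ROLES = (ROLE_MEG, ROLE_MOG, ROLE_MCG, ROLE_TRIGGER)


@dataclass
class Recording:
    """A continuous multichannel magnetometer recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in arbitrary but
        internally consistent field units.
    sampling_rate
        Sampling frequency in Hz.
    channel_roles
        One role per channel, each from ``{MEG, MOG_REF, MCG_REF, TRIGGER}``.
        Exactly one MOG_REF, one MCG_REF and one TRIGGER channel must be
        present.
    """

    data: np.ndarray
    sampling_rate: float
    channel_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("one role is required per channel")
        for role in self.channel_roles:
            if role not in ALL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        for role in (ROLE_MOG, ROLE_MCG, ROLE_TRIGGER):
            if self.channel_roles.count(role) != 1:
                raise ValueError(f"exactly one {role} channel is required")

    # -- role-based accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def meg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r == ROLE_MEG]
        )

    def _single(self, role: str) -> int:
        return self.channel_roles.index(role)

    @property
    def mog_index(self) -> int:
        return self._single(ROLE_MOG)

    @property
    def mcg_index(self) -> int:
        return self._single(ROLE_MCG)

    @property
    def trigger_index(self) -> int:
        return self._single(ROLE_TRIGGER)

    @property
    def meg(self) -> np.ndarray:
        """The MEG-role rows, shape ``(n_meg, n_samples)``."""
        return self.data[self.meg_indices]

    @property
    def mog(self) -> np.ndarray:
        return self.data[self.mog_index]

    @property
    def mcg(self) -> np.ndarray:
        return self.data[self.mcg_index]

    @property
    def trigger(self) -> np.ndarray:
        return self.data[self.trigger_index]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.sampling_rate, list(self.channel_roles)
        )

    # -- persistence ----------------------------------------------------------

    def to_hdf5(self, path, ground_truth=None) -> None:
        """Write the recording (and optionally its ground truth) to HDF5."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["channel_roles"] = [r.encode() for r in self.channel_roles]
            if ground_truth is not None:
                g = f.create_group("sources")
                g.create_dataset("blink", data=ground_truth.blink_source)
                g.create_dataset("cardiac", data=ground_truth.cardiac_source)
                g.create_dataset("evoked", data=ground_truth.erf_source)
                f.create_dataset(
                    "trigger_onsets", data=ground_truth.trigger_onsets
                )
                t = f.create_group("topographies")
                for name, vec in ground_truth.mixing_topographies.items():
                    t.create_dataset(name, data=vec)

    @classmethod
    def from_fif(cls, path, role_map: dict | None = None) -> "Recording":  # pragma: no cover
        """Import a FIF-format recording (requires ``mne``).

        ``role_map`` maps channel names to roles; unmapped channels get a
        role from their FIF type (meg -> MEG, eog -> MOG_REF, ecg ->
        MCG_REF, stim -> TRIGGER); everything else is dropped.  The result
        must satisfy the one-MOG/one-MCG/one-TRIGGER contract.
        """
        import mne

        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        type_to_role = {
            "mag": ROLE_MEG, "grad": ROLE_MEG, "eog": ROLE_MOG,
            "ecg": ROLE_MCG, "stim": ROLE_TRIGGER,
        }
        role_map = role_map or {}
        rows, roles = [], []
        for idx, name in enumerate(raw.ch_names):
            role = role_map.get(name, type_to_role.get(raw.get_channel_types()[idx]))
            if role is None:
                continue
            rows.append(idx)
            roles.append(role)
        return cls(raw.get_data(picks=rows), raw.info["sfreq"], roles)

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            fs = float(f.attrs["sampling_rate"])
            roles = [
                r.decode() if isinstance(r, bytes) else str(r)
                for r in f.attrs["channel_roles"]
            ]
        return cls(data, fs, roles)
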