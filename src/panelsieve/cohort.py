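"""Core cohort container: binary mutation matrix joined with clinical outcomes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATED = "treated"
CONTROL = "control"

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
RESPONDER_CATEGORIES = ("CR", "PR")


@dataclass
class CohortDataset:
    """A patient x gene binary mutation matrix with per-patient clinical outcomes.

    Parameters
    ----------
    patient_ids : list of str
        Unique sample identifiers, one per matrix row.
    genes : list of str
        Unique gene symbols, one per matrix column.
    mutations : ndarray of shape (n_patients, n_genes)
        Strictly binary (0/1) mutation indicator matrix.
    arm : ndarray of str
        Per-patient treatment arm, ``"treated"`` or ``"control"``.
    pfs_time, os_time : ndarray of float
        Positive survival times in months.
    pfs_event, os_event : ndarray of int
        Event indicators, 1 = event observed, 0 = censored.
    response : ndarray of str, optional
        RECIST best response per patient (CR/PR/SD/PD/NE).
    sld : ndarray of float, optional
        Baseline sum of longest diameters, millimetres.
    tmb : ndarray of float, optional
        Tumor mutational burden, mutations per megabase.
    truth : list of str, optional
        Planted benefit genes (simulated cohorts only).
    """

    patient_ids: list[str]
    genes: list[str]
    mutations: np.ndarray
    arm: np.ndarray
    pfs_time: np.ndarray
    pfs_event: np.ndarray
    os_time: np.ndarray
    os_event: np.ndarray
    response: np.ndarray | None = None
    sld: np.ndarray | None = None
    tmb: np.ndarray | None = None
    truth: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mutations = np.asarray(self.mutations, dtype=np.int8)
        self.arm = np.asarray(self.arm, dtype=object)
        self.pfs_time = np.asarray(self.pfs_time, dtype=float)
        self.pfs_event = np.asarray(self.pfs_event, dtype=int)
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event, dtype=int)
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=object)
        if self.sld is not None:
            self.sld = np.asarray(self.sld, dtype=float)
        if self.tmb is not None:
            self.tmb = np.asarray(self.tmb, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n, g = len(self.patient_ids), len(self.genes)
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if len(set(self.genes)) != g:
            raise ValueError("duplicate gene symbols")
        if self.mutations.shape != (n, g):
            raise ValueError(
                f"mutation matrix shape {self.mutations.shape} does not match "
                f"{n} patients x {g} genes"
            )
        if not np.isin(self.mutations, (0, 1)).all():
            raise ValueError("mutation matrix must be strictly binary")
        for name, arr in (
            ("arm", self.arm),
            ("pfs_time", self.pfs_time),
            ("pfs_event", self.pfs_event),
            ("os_time", self.os_time),
            ("os_event", self.os_event),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} patients")
        bad_arm = set(self.arm) - {TREATED, CONTROL}
        if bad_arm:
            raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
        for name, t in (("pfs_time", self.pfs_time), ("os_time", self.os_time)):
            if not (t > 0).all():
                raise ValueError(f"{name} must be strictly positive")
        for name, e in (("pfs_event", self.pfs_event), ("os_event", self.os_event)):
            if not np.isin(e, (0, 1)).all():
                raise ValueError(f"{name} must be 0/1")
        if self.response is not None:
            bad = set(self.response) - set(RESPONSE_CATEGORIES)
            if bad:
                raise ValueError(f"unknown response categories: {sorted(bad)}")

    # -- convenience --------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def treated_mask(self) -> np.ndarray:
        return self.arm == TREATED

    def gene_index(self, symbols: list[str]) -> np.ndarray:
        """Column indices of the given symbols; absent symbols are skipped."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[s] for s in symbols if s in lookup], dtype=int)

    def subset(self, mask: np.ndarray) -> "CohortDataset":
        """Row-subset the cohort by a boolean mask or index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortDataset(
            patient_ids=[self.patient_ids[i] for i in idx],
            genes=list(self.genes),
            mutations=self.mutations[idx],
            arm=self.arm[idx],
            pfs_time=self.pfs_time[idx],
            pfs_event=self.pfs_event[idx],
            os_time=self.os_time[idx],
            os_event=self.os_event[idx],
            response=None if self.response is None else self.response[idx],
            sld=None if self.sld is None else self.sld[idx],
            tmb=None if self.tmb is None else self.tmb[idx],
            truth=self.truth,
        )

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical table as a DataFrame (one row per patient)."""
        data = {
            "sample_id": self.patient_ids,
            "arm": self.arm,
            "pfs_time": self.pfs_time,
            "pfs_event": self.pfs_event,
            "os_time": self.os_time,
            "os_event": self.os_event,
        }
        if self.response is not None:
            data["response"] = self.response
        if self.sld is not None:
            data["sld"] = self.sld
        if self.tmb is not None:
            data["tmb"] = self.tmb
        return pd.DataFrame(data)
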