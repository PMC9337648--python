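"""Whole simulated observer studies with known ground truth.

A study emulates the clinical protocol: each volunteer's two lobes are
scanned by every observer in several repeats, with both a 2D caliper
measurement pair and a tracked sweep pair per (volunteer, observer,
repeat).  The analytic phantom volume stands in for the MRI reference.

Sweeps are generated lazily and deterministically: `sweep_for(...)`
rebuilds any single sweep from the study seed without materializing the
full set (a 28×3×3 study holds 504 sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import (
    AcquisitionParams,
    ObserverProfile,
    default_observers,
    simulate_caliper,
    simulate_sweep,
)
from .phantom import CohortParams, LobePhantom, make_isthmus, sample_lobe_phantom, sample_total_volume
from .rng import spawn_key, split_rng
from .volumetry import ellipsoid_volume, total_volume

__all__ = ["StudyData", "generate_study"]

SIDES = ("left", "right")


@dataclass
class StudyData:
    """Phantoms, 2D measurements, and lazy sweep access for one cohort."""

    seed: int
    phantoms: dict          # (volunteer, side) -> LobePhantom
    observers: tuple
    n_repeats: int
    acquisition: AcquisitionParams
    table_2d: pd.DataFrame        # volunteer, observer, repeat, modality, volume_ml, reference_ml
    reference: pd.Series          # volunteer -> total true volume (ml)
    isthmi: dict = None           # volunteer -> isthmus phantom (only if enabled)

    @property
    def volunteers(self) -> list:
        return sorted({v for v, _ in self.phantoms})

    @property
    def sweep_index(self) -> list[tuple]:
        """All (volunteer, observer_name, repeat) sweep-pair identifiers."""
        return [
            (v, o.name, r)
            for v in self.volunteers
            for o in self.observers
            for r in range(1, self.n_repeats + 1)
        ]

    def observer(self, name: str) -> ObserverProfile:
        for o in self.observers:
            if o.name == name:
                return o
        raise KeyError(f"unknown observer {name!r}")

    def sweep_for(self, volunteer: int, observer: str, repeat: int, side: str):
        """Deterministically (re)generate one tracked sweep."""
        if side not in SIDES:
            raise ValueError("side must be 'left' or 'right'")
        obs = self.observer(observer)
        seed = _stage_seed(self.seed, "sweep", volunteer, observer, repeat, side)
        companions = ()
        if self.isthmi and volunteer in self.isthmi:
            companions = (self.isthmi[volunteer],)
        return simulate_sweep(self.phantoms[(volunteer, side)], obs, self.acquisition, seed,
                              companions=companions)


def _stage_seed(master: int, *tags) -> int:
    """A sub-seed below 2^31 unique to (master, tags)."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=spawn_key(*tags))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def generate_study(
    n_volunteers: int = 28,
    observers: tuple[ObserverProfile, ...] | None = None,
    n_repeats: int = 3,
    seed: int = 0,
    cohort: CohortParams | None = None,
    acquisition: AcquisitionParams | None = None,
) -> StudyData:
    """Simulate a full observer study.

    Defaults follow the clinical design: 28 volunteers × 3 observers × 3
    repeats, 2D caliper and 3D sweep acquisitions per session, analytic
    ground truth as the reference column.  The 2D ellipsoid-formula volumes
    are computed eagerly (they are cheap); sweeps are exposed lazily through
    :meth:`StudyData.sweep_for`.
    """
    if n_volunteers < 1 or n_repeats < 1:
        raise ValueError("n_volunteers and n_repeats must be >= 1")
    observers = tuple(observers) if observers is not None else default_observers()
    if len({o.name for o in observers}) != len(observers):
        raise ValueError("observer names must be unique")
    cohort = cohort or CohortParams()
    cohort.validate()
    acquisition = acquisition or AcquisitionParams()

    phantoms: dict = {}
    ref_rows = {}
    for v in range(1, n_volunteers + 1):
        rng_v = split_rng(seed, "volunteer", v)
        total = sample_total_volume(cohort, rng_v)
        frac = rng_v.uniform(cohort.lobe_split_low, cohort.lobe_split_high)
        targets = {"left": total * frac, "right": total * (1.0 - frac)}
        for side in SIDES:
            phantoms[(v, side)] = sample_lobe_phantom(
                cohort,
                seed=_stage_seed(seed, "phantom", v, side),
                side=side,
                target_volume_ml=targets[side],
            )
        ref_rows[v] = sum(phantoms[(v, s)].true_volume for s in SIDES)
    reference = pd.Series(ref_rows, name="reference_ml")
    isthmi = {}
    if cohort.isthmus:
        isthmi = {v: make_isthmus(phantoms[(v, "left")], phantoms[(v, "right")])
                  for v in range(1, n_volunteers + 1)}

    records = []
    for v in range(1, n_volunteers + 1):
        for obs in observers:
            for rep in range(1, n_repeats + 1):
                lobes = {}
                for side in SIDES:
                    cal = simulate_caliper(
                        phantoms[(v, side)], obs,
                        seed=_stage_seed(seed, "caliper", v, obs.name, rep, side),
                    )
                    lobes[side] = ellipsoid_volume(cal, observer=obs.name, repeat=rep)
                tot = total_volume(lobes["left"], lobes["right"])
                records.append(
                    {
                        "volunteer": v,
                        "observer": obs.name,
                        "repeat": rep,
                        "modality": "2D",
                        "volume_ml": tot.volume,
                        "reference_ml": ref_rows[v],
                    }
                )
    table_2d = pd.DataFrame.from_records(records)

    return StudyData(
        seed=seed,
        phantoms=phantoms,
        observers=observers,
        n_repeats=n_repeats,
        acquisition=acquisition,
        table_2d=table_2d,
        reference=reference,
        isthmi=isthmi,
    )
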