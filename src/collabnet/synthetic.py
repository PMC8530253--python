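"""Seeded synthetic NICU audit-log generator.

Real NICU audit logs are protected data, so every pipeline stage is
exercised on synthetic logs whose *structure* — a bipartite clinician ×
patient-day event stream over a rostered multidisciplinary team — matches
what the analysis assumes.  The generative model is a deliberately simple
staffing mechanism with three independent knobs, one per reported
structural effect:

* **Pods with shift-based nursing.**  Nurses (and NPs, residents,
  respiratory therapists) are partitioned into pods; each patient is
  admitted to a pod and is covered every day by ``nurses_per_patient_day``
  shifts of pod nurses, each bedside nurse taking ``patients_per_nurse``
  patients, with a *cross-coverage* probability of any slot being filled
  from the whole unit and a boarding probability (``pod_mixing_prob``) of a
  patient being handled by the next pod over for a day.  Several shifts a
  day plus high cross-coverage produce a dense nurse web (high nurse
  eigenvector centrality, short paths); one nurse per patient per day with
  near-zero cross-coverage removes same-day nurse-nurse co-occurrence
  almost entirely.
* **Attending coverage.**  In cohorted mode (``physician_cohort_pods``)
  each neonatologist is fixed to a small span of adjacent pods and charts
  on at most ``physician_patients_per_day`` patients on a charting day
  (``physician_day_prob``); in unit-wide mode the daily census is split
  into blocks covered by a rotating attending.  Sparse, pod-local
  charting keeps pre-era physicians peripheral; daily charting over a
  two-pod span makes pandemic-era physicians the only systematic
  inter-pod bridges, which is what raises their betweenness and stretches
  path lengths.
* **Pendant consults.**  Occasional one-off support-staff and cardiac
  ICU nurse consults hang off the periphery and stretch path lengths.

Two shipped presets, ``pre_like`` and ``intra_like``, encode a
high-mixing and a distanced/isolated staffing regime respectively.  The
parameters are honest knobs of this toy mechanism, not estimates of any
real unit's staffing.

All randomness flows from one root seed through fixed per-stage
substreams, so identical (config, seed) pairs give byte-identical CSVs and
adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audit_log import ACTION_CATEGORIES, EVENT_COLUMNS

#: Normal 75th-percentile z, used to convert an IQR target to a lognormal σ.
_Z75 = 0.6744897501960817

ID_PREFIX = {
    "nicu_nurse": "rn",
    "nurse_practitioner": "np",
    "resident": "md",
    "respiratory_therapist": "rt",
    "cardiac_icu_nurse": "cn",
    "neonatologist": "neo",
    "support": "sp",
}

#: Specialties staffed out of pods (sticky sub-teams); others are unit-wide.
POD_SPECIALTIES = (
    "nicu_nurse", "nurse_practitioner", "resident", "respiratory_therapist",
)

DEFAULT_ROSTER_SIZES = {
    "nicu_nurse": 120,
    "nurse_practitioner": 12,
    "resident": 20,
    "respiratory_therapist": 15,
    "cardiac_icu_nurse": 10,
    "neonatologist": 6,
    "support": 30,
}

#: Event-category mix for emitted actions (notes/orders dominate real logs).
CATEGORY_PROBS = {
    "condition": 0.10,
    "procedure": 0.05,
    "medication": 0.15,
    "note": 0.30,
    "order": 0.25,
    "measurement": 0.15,
}


class GeneratorError(ValueError):
    pass


@dataclass
class RegimeConfig:
    """All parameters of one staffing regime.

    Probabilities are per-slot or per-patient-day as documented on each
    field; counts are roster or census sizes.  ``los_median`` and
    ``los_iqr`` are sample targets for the lognormal length-of-stay draw
    (the σ is fitted to the q3/q1 ratio, so the realised quartiles match
    the target ratio around the target median).
    """

    label: str = "pre_like"
    n_patients: int = 386
    admission_start: dt.date = dt.date(2019, 9, 1)
    admission_end: dt.date = dt.date(2019, 12, 31)
    los_median: float = 10.0
    los_iqr: tuple[float, float] = (4.0, 20.0)
    roster_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROSTER_SIZES))
    pod_count: int = 6
    nurses_per_patient_day: int = 3
    patients_per_nurse: int = 2
    nurse_cross_coverage_prob: float = 0.30
    pod_mixing_prob: float = 0.10
    physician_patients_per_day: int = 2
    physician_day_prob: float = 0.35
    physician_rotation_days: int = 7
    physician_cohort_pods: int | None = 1
    staffing_probs: dict[str, float] = field(default_factory=lambda: {
        "nurse_practitioner": 0.35,
        "resident": 0.30,
        "respiratory_therapist": 0.45,
    })
    cardiac_consult_prob: float = 0.10
    cardiac_day_prob: float = 0.30
    consult_event_rate: float = 0.03
    unknown_sex_fraction: float = 0.176
    race_probs: dict[str, float] = field(default_factory=lambda: {
        "white": 0.668, "african_american": 0.166, "asian": 0.041,
        "other": 0.125,
    })
    ethnicity_probs: dict[str, float] = field(default_factory=lambda: {
        "non_hispanic": 0.858, "latino": 0.130, "unknown": 0.012,
    })
    disposition_probs: dict[str, float] = field(default_factory=lambda: {
        "home": 0.917, "expired": 0.070, "hospice": 0.005,
        "short_term_hospital": 0.008, "other": 0.0,
    })

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = [self.nurse_cross_coverage_prob, self.pod_mixing_prob,
                 self.cardiac_consult_prob, self.cardiac_day_prob,
                 self.physician_day_prob,
                 self.consult_event_rate, self.unknown_sex_fraction,
                 *self.staffing_probs.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise GeneratorError("all probabilities must lie in [0, 1]")
        if self.n_patients < 1:
            raise GeneratorError("n_patients must be >= 1")
        if any(v < 0 for v in self.roster_sizes.values()):
            raise GeneratorError("roster sizes must be >= 0")
        if min(self.pod_count, self.patients_per_nurse,
               self.nurses_per_patient_day, self.physician_patients_per_day,
               self.physician_rotation_days) < 1:
            raise GeneratorError("pod/team/census sizes must be >= 1")
        if self.physician_cohort_pods is not None and not (
            1 <= self.physician_cohort_pods <= self.pod_count
        ):
            raise GeneratorError("physician_cohort_pods must be in [1, pod_count]")
        q1, q3 = self.los_iqr
        if not (0 < q1 < q3):
            raise GeneratorError(f"infeasible LOS IQR target {self.los_iqr}")
        if self.admission_end < self.admission_start:
            raise GeneratorError("admission window end precedes start")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["admission_start"] = self.admission_start.isoformat()
        d["admission_end"] = self.admission_end.isoformat()
        d["los_iqr"] = list(self.los_iqr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeConfig":
        d = dict(d)
        for k in ("admission_start", "admission_end"):
            if isinstance(d.get(k), str):
                d[k] = dt.date.fromisoformat(d[k])
        if "los_iqr" in d:
            d["los_iqr"] = tuple(d["los_iqr"])
        return cls(**d)


def preset(label: str) -> RegimeConfig:
    """The two shipped regimes.

    ``pre_like`` is the high-mixing baseline; ``intra_like`` is the
    distanced regime: single-nurse 1:1 bedside coverage, near-zero
    cross-coverage and boarding, and physicians charting daily over a
    two-pod cohort span (the only systematic inter-pod ties).
    """
    if label == "pre_like":
        return RegimeConfig()
    if label == "intra_like":
        return RegimeConfig(
            label="intra_like",
            n_patients=326,
            admission_start=dt.date(2020, 3, 1),
            admission_end=dt.date(2020, 6, 30),
            los_median=9.0,
            los_iqr=(3.3, 21.8),
            pod_count=6,
            nurses_per_patient_day=1,
            patients_per_nurse=1,
            nurse_cross_coverage_prob=0.02,
            pod_mixing_prob=0.02,
            physician_patients_per_day=18,
            physician_day_prob=1.0,
            physician_rotation_days=7,
            physician_cohort_pods=2,
            staffing_probs={
                "nurse_practitioner": 0.4,
                "resident": 0.25,
                "respiratory_therapist": 0.6,
            },
            unknown_sex_fraction=0.178,
            race_probs={"white": 0.709, "african_american": 0.132,
                        "asian": 0.018, "other": 0.141},
            ethnicity_probs={"non_hispanic": 0.868, "latino": 0.098,
                             "unknown": 0.034},
            disposition_probs={"home": 0.917, "expired": 0.049,
                               "hospice": 0.006, "short_term_hospital": 0.025,
                               "other": 0.003},
        )
    raise GeneratorError(f"unknown preset {label!r}; use pre_like or intra_like")


def scaled_preset(label: str, n_patients: int) -> RegimeConfig:
    """A preset scaled to a smaller cohort with proportional staffing.

    Roster sizes shrink with the census (with small floors so every
    specialty stays represented and rotations remain possible), and the
    pod count shrinks so pods keep a workable nurse pool.  Running a small
    cohort against the full-unit roster instead would leave the unit so
    underloaded that network structure (hub identity, diameter) is
    dominated by seed noise rather than staffing design.
    """
    cfg = preset(label)
    scale = n_patients / cfg.n_patients
    # floors keep a workable core team: at least a two-pod nursing staff,
    # small frontline pools, and the full attending group (the physician
    # rotation does not shrink with the census)
    floors = {"nicu_nurse": 18, "nurse_practitioner": 4, "resident": 5,
              "respiratory_therapist": 4, "cardiac_icu_nurse": 3,
              "neonatologist": 6, "support": 6}
    cfg.n_patients = n_patients
    cfg.roster_sizes = {
        spec: max(floors.get(spec, 1), round(n * scale))
        for spec, n in cfg.roster_sizes.items()
    }
    # pods of roughly nine nurses
    cfg.pod_count = max(1, min(cfg.pod_count,
                               cfg.roster_sizes["nicu_nurse"] // 9))
    if cfg.physician_cohort_pods is not None:
        cfg.physician_cohort_pods = min(cfg.physician_cohort_pods,
                                        cfg.pod_count)
    cfg.validate()
    return cfg


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Per-stage substream off the root seed (stages never interact)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _pick(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=p / p.sum()))


def _allocate(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    """Exact-count categorical allocation (largest remainder), shuffled.

    Published cohort tables give counts, not sampling probabilities, so
    demographic marginals are reproduced exactly at any n instead of being
    re-drawn i.i.d.; only the assignment to patients is random.
    """
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    base = np.floor(p * n).astype(int)
    frac = p * n - base
    for i in np.argsort(-frac)[: n - base.sum()]:
        base[i] += 1
    return rng.permutation(np.repeat(keys, base))


def generate_patients(config: RegimeConfig, seed: int) -> pd.DataFrame:
    """Draw the patient table for one regime.

    Admissions are uniform over the window; length of stay is lognormal
    with the sample median targeting ``los_median`` and σ fitted to the
    target q3/q1 ratio, rounded to whole days (minimum 1).  Demographics
    and dispositions follow the configured proportions.  Deterministic
    given (config, seed).
    """
    config.validate()
    rng = _rng(seed, 11)
    n = config.n_patients
    window = (config.admission_end - config.admission_start).days + 1
    offsets = rng.integers(0, window, size=n)
    admit = [config.admission_start + dt.timedelta(days=int(o)) for o in offsets]

    q1, q3 = config.los_iqr
    sigma = np.log(q3 / q1) / (2 * _Z75)
    los = np.maximum(
        1, np.rint(rng.lognormal(np.log(config.los_median), sigma, size=n))
    ).astype(int)

    u = config.unknown_sex_fraction
    sex = _allocate(rng, {"female": (1 - u) / 2, "male": (1 - u) / 2,
                          "unknown": u}, n)
    race = _allocate(rng, config.race_probs, n)
    eth = _allocate(rng, config.ethnicity_probs, n)
    dispo = _allocate(rng, config.disposition_probs, n)
    # age at admission in days: overwhelmingly day-of-birth admissions,
    # with a thin tail of outborn transfers up to a few months old
    age = np.where(rng.random(n) < 0.8, 0,
                   np.minimum(rng.geometric(0.05, size=n), 150))

    return pd.DataFrame({
        "patient_id": [f"{config.label[:1]}p{i:04d}" for i in range(n)],
        "admit_date": admit,
        "discharge_date": [a + dt.timedelta(days=int(l)) for a, l in zip(admit, los)],
        "sex": sex,
        "race": race,
        "ethnicity": eth,
        "age_days": age,
        "disposition": dispo,
        "excluded": False,
        "los_days": los,
    })


def make_roster(config: RegimeConfig, seed: int) -> pd.DataFrame:
    """Roster frame: clinician_id, specialty, pod (-1 for unit-wide roles)."""
    rows = []
    for spec, size in config.roster_sizes.items():
        prefix = ID_PREFIX.get(spec, spec[:2])
        for i in range(size):
            pod = i % config.pod_count if spec in POD_SPECIALTIES else -1
            rows.append({
                "clinician_id": f"{prefix}{i:03d}",
                "specialty": spec,
                "pod": pod,
            })
    return pd.DataFrame(rows, columns=["clinician_id", "specialty", "pod"])


def _pools(roster: pd.DataFrame, config: RegimeConfig) -> dict:
    pools: dict = {"by_pod": {}, "all": {}}
    for spec in ID_PREFIX:
        ids = roster.loc[roster["specialty"] == spec, "clinician_id"].tolist()
        pools["all"][spec] = ids
    for spec in POD_SPECIALTIES:
        sub = roster[roster["specialty"] == spec]
        pools["by_pod"][spec] = {
            pod: grp["clinician_id"].tolist() for pod, grp in sub.groupby("pod")
        }
    return pools


def _check_staffing(pools: dict, config: RegimeConfig) -> None:
    nurse_pods = pools["by_pod"].get("nicu_nurse", {})
    if any(not nurse_pods.get(p) for p in range(config.pod_count)):
        raise GeneratorError(
            "roster too small for staffing: specialty 'nicu_nurse' leaves "
            f"some of the {config.pod_count} pods without nurses"
        )
    if not pools["all"]["neonatologist"]:
        raise GeneratorError(
            "roster too small for staffing: specialty 'neonatologist' is empty")
    for spec, prob in config.staffing_probs.items():
        if prob > 0 and not pools["all"].get(spec):
            raise GeneratorError(
                f"roster too small for staffing: specialty {spec!r} is empty")
    if config.cardiac_consult_prob > 0 and not pools["all"]["cardiac_icu_nurse"]:
        raise GeneratorError(
            "roster too small for staffing: specialty 'cardiac_icu_nurse' is empty")
    if config.consult_event_rate > 0 and not pools["all"]["support"]:
        raise GeneratorError(
            "roster too small for staffing: specialty 'support' is empty")


def generate_events(
    patients: pd.DataFrame,
    roster: pd.DataFrame,
    config: RegimeConfig,
    seed: int,
) -> pd.DataFrame:
    """Emit the action-event log for one regime.

    For every day of every stay the patient is staffed with bedside
    nurse(s), one neonatologist from the rotating census-block schedule,
    and probabilistic NP / resident / respiratory-therapist coverage from
    the patient's pod; occasional cardiac-ICU-nurse and support consults
    are attached.  Each assignment emits 1-5 events with categories from
    the configured mix.  Deterministic given (patients, roster, config,
    seed).
    """
    config.validate()
    rng = _rng(seed, 13)
    pools = _pools(roster, config)
    _check_staffing(pools, config)
    nurse_all = pools["all"]["nicu_nurse"]
    phys = pools["all"]["neonatologist"]
    cat_names = list(ACTION_CATEGORIES)
    cat_p = np.asarray([CATEGORY_PROBS[c] for c in cat_names])
    cat_p = cat_p / cat_p.sum()

    # --- per-patient sticky assignments -----------------------------------
    assign: dict[str, dict] = {}
    for row in patients.itertuples(index=False):
        pod = int(rng.integers(config.pod_count))
        primaries = {}
        for spec in ("nurse_practitioner", "resident", "respiratory_therapist"):
            pool = pools["by_pod"].get(spec, {}).get(pod) or pools["all"][spec]
            if pool:
                primaries[spec] = str(rng.choice(pool))
        cardiac = (str(rng.choice(pools["all"]["cardiac_icu_nurse"]))
                   if config.cardiac_consult_prob > 0
                   and rng.random() < config.cardiac_consult_prob else None)
        assign[row.patient_id] = {
            "pod": pod, "primaries": primaries, "cardiac": cardiac,
        }

    # --- census calendar --------------------------------------------------
    # a stay occupies LOS calendar days: admission day up to (not including)
    # the discharge date, so a 1-day stay is a single patient-day
    stays: dict[dt.date, list[str]] = {}
    for row in patients.itertuples(index=False):
        d = row.admit_date
        while d < row.discharge_date:
            stays.setdefault(d, []).append(row.patient_id)
            d += dt.timedelta(days=1)

    specialty_of = dict(zip(roster["clinician_id"], roster["specialty"]))
    day0 = min(stays) if stays else config.admission_start
    records: list[tuple] = []

    def emit(clin: str, pid: str, day: dt.date) -> None:
        n_ev = int(rng.integers(1, 6))
        secs = rng.integers(0, 86400, size=n_ev)
        cats = rng.choice(cat_names, size=n_ev, p=cat_p)
        for s, c in zip(secs, cats):
            ts = dt.datetime.combine(day, dt.time()) + dt.timedelta(seconds=int(s))
            records.append((clin, specialty_of[clin], pid, ts, c))

    span = config.physician_cohort_pods
    for day in sorted(stays):
        census = sorted(stays[day])
        rota = ((day - day0).days) // config.physician_rotation_days
        if span is None:
            # unit-wide census blocks, attending rotates across blocks
            for b_start in range(0, len(census), config.physician_patients_per_day):
                block = census[b_start:b_start + config.physician_patients_per_day]
                doc = phys[(b_start // config.physician_patients_per_day + rota)
                           % len(phys)]
                if rng.random() >= config.physician_day_prob:
                    continue
                for pid in block:
                    emit(doc, pid, day)
        else:
            # cohorted attendings: physician i is fixed to the adjacent pod
            # span {i, .., i+span-1}; pod p alternates among its span owners.
            # The attending charts on at most physician_patients_per_day of
            # the pod census per day (the rest is frontline-provider work).
            pods_today: dict[int, list[str]] = {}
            for pid in census:
                pods_today.setdefault(assign[pid]["pod"], []).append(pid)
            for pod in sorted(pods_today):
                owners = sorted({(pod - j) % config.pod_count for j in range(span)})
                doc = phys[owners[rota % len(owners)] % len(phys)]
                if rng.random() >= config.physician_day_prob:
                    continue
                pod_census = pods_today[pod]
                cap = config.physician_patients_per_day
                if len(pod_census) > cap:
                    pod_census = sorted(rng.choice(pod_census, size=cap,
                                                   replace=False))
                for pid in pod_census:
                    emit(doc, pid, day)
        # shift-based nursing: per pod and shift, enough nurses come on to
        # cover the pod census at `patients_per_nurse` patients each, and
        # the census is dealt round-robin among them.  Boarded patients
        # (pod_mixing_prob per day) are covered by the next pod over.
        by_pod: dict[int, list[str]] = {p: [] for p in range(config.pod_count)}
        for pid in census:
            pod = assign[pid]["pod"]
            if rng.random() < config.pod_mixing_prob:
                pod = (pod + 1) % config.pod_count
            by_pod[pod].append(pid)
        for pod in range(config.pod_count):
            pod_census = by_pod[pod]
            if not pod_census:
                continue
            pool = pools["by_pod"]["nicu_nurse"][pod]
            k = -(-len(pod_census) // config.patients_per_nurse)
            for _shift in range(config.nurses_per_patient_day):
                on_shift = list(rng.choice(pool, size=min(k, len(pool)),
                                           replace=False))
                for i in range(len(on_shift)):
                    if rng.random() < config.nurse_cross_coverage_prob:
                        on_shift[i] = str(rng.choice(nurse_all))
                for i, pid in enumerate(pod_census):
                    emit(on_shift[i % len(on_shift)], pid, day)
        for pid in census:
            a = assign[pid]
            pod = a["pod"]
            for spec, prob in config.staffing_probs.items():
                if spec not in a["primaries"] or rng.random() >= prob:
                    continue
                if rng.random() < config.nurse_cross_coverage_prob:
                    pool = pools["by_pod"].get(spec, {}).get(pod) or pools["all"][spec]
                    clin = str(rng.choice(pool))
                else:
                    clin = a["primaries"][spec]
                emit(clin, pid, day)
            if a["cardiac"] and rng.random() < config.cardiac_day_prob:
                emit(a["cardiac"], pid, day)
            if config.consult_event_rate > 0 and rng.random() < config.consult_event_rate:
                emit(str(rng.choice(pools["all"]["support"])), pid, day)

    events = pd.DataFrame(records, columns=list(EVENT_COLUMNS))
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    events["day"] = events["timestamp"].dt.date
    return events.sort_values(
        ["day", "clinician_id", "patient_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)


def generate_regime(
    config: RegimeConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: (patients, roster, events) for one regime."""
    patients = generate_patients(config, seed)
    roster = make_roster(config, seed)
    events = generate_events(patients, roster, config, seed)
    return patients, roster, events
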