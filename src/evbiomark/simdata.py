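"""Synthetic plasma-EV small-RNA-seq data with known ground truth.

The generator emulates a case/control surgery-intervention design: healthy
controls (HC) plus patients sampled before (PreOp) and ~one week after
(PostOp) tumor resection.  Its causal premise is that a patient's plasma EV
pool is a mixture of a constitutive baseline component and a tumor-derived
component whose weight ``tau_i`` (the patient's tumor-EV fraction) collapses
to ``postop_residual * tau_i`` once the tumor is removed.  The tumor
component (a) shifts biotype-level composition (miRNA/snRNA/snoRNA/tRF
enriched, lncRNA depleted, by default) and (b) carries tumor-specific
planted marker RNAs that are absent from the baseline — so planted markers
are never seen in controls, appear in the subset of patients whose tumor
expresses them, and drop after surgery.

Counts are negative binomial around the mixture expectation, with
lognormal library sizes and a lognormal subject effect shared between a
patient's paired samples.  Everything is deterministic given the config
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord
from .annotation import BIOTYPES, FeatureAnnotation
from .countmatrix import CountMatrix, SampleTable
from .quantify import PRIORITY_ORDER, overlap_length

#: Baseline biotype composition of EV-borne reads. The four major classes
#: (lncRNA, mRNA, miRNA, piRNA) take the fractions observed in plasma EVs;
#: the six minor classes share the remainder.
DEFAULT_BIOTYPE_PROPORTIONS: dict[str, float] = {
    "lncRNA": 0.283,
    "mRNA": 0.273,
    "miRNA": 0.186,
    "piRNA": 0.199,
    "tRNA": 0.012,
    "rRNA": 0.010,
    "pseudogene": 0.008,
    "snRNA": 0.010,
    "snoRNA": 0.012,
    "miscRNA": 0.007,
}

#: Multiplicative enrichment of each biotype inside the tumor-derived
#: component: small structural RNAs up, lncRNA down.
DEFAULT_COMPOSITION_SHIFT: dict[str, float] = {
    "miRNA": 2.0,
    "snRNA": 2.0,
    "snoRNA": 2.0,
    "tRNA": 2.0,
    "lncRNA": 0.4,
}

#: Clinical variable marginals for a 32-patient locally advanced breast
#: cancer cohort (counts out of 32).
CLINICAL_MARGINALS: dict[str, dict] = {
    "ER": {"positive": 20, "negative": 12},
    "PR": {"positive": 17, "negative": 15},
    "HER2_IHC": {0: 5, 1: 13, 2: 4, 3: 10},
    "grade": {2: 21, 3: 11},
    "T_stage": {1: 2, 2: 12, 3: 16, 4: 2},
    "TNBC": {"yes": 8, "no": 24},
    "E_cadherin": {"positive": 22, "negative": 10},
    "Ki67": {"<=14%": 5, ">14%": 27},
}


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the study design the pipeline targets: 30 controls, 32
    patients with paired PreOp/PostOp samples, ~1.3 million mapped reads
    per library, NB dispersion 0.3, tumor-EV fraction tau ~ Beta(2, 8)
    (low and variable), post-surgery residual 0.1, and 2 planted
    tumor-specific markers per biotype each expressed by a given tumor
    with probability 0.2.
    """

    n_hc: int = 30
    n_patients: int = 32
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    n_features_per_biotype: dict[str, int] | int = 50
    lib_size_mean: float = 1.3e6
    lib_size_cv: float = 0.3
    dispersion: float | dict[str, float] = 0.3
    tau_alpha: float = 2.0
    tau_beta: float = 8.0
    postop_residual: float = 0.1
    n_planted_per_biotype: int = 2
    marker_prevalence: float = 0.2
    composition_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_SHIFT)
    )
    #: Fraction of the tumor component's reads allocated to each planted
    #: marker the tumor expresses.
    marker_mass: float = 0.005
    subject_sd: float = 0.2
    #: Fraction of features given a same-strand cross-biotype overlapping
    #: partner in the toy annotation.
    overlap_fraction: float = 0.2
    read_length: int = 25
    n_reads_per_sample: int = 1000
    #: Planted markers whose carriage is restricted to ER-positive (resp.
    #: HER2 IHC-3) tumors, carried there with probability
    #: ``linked_prevalence``.
    er_linked_markers: int = 0
    her2_linked_markers: int = 0
    linked_prevalence: float = 0.8
    seed: int = 0

    def features_per_biotype(self, biotype: str) -> int:
        if isinstance(self.n_features_per_biotype, Mapping):
            return int(self.n_features_per_biotype.get(biotype, 0))
        return int(self.n_features_per_biotype)

    def dispersion_for(self, biotype: str) -> float:
        if isinstance(self.dispersion, Mapping):
            return float(self.dispersion.get(biotype, 0.0))
        return float(self.dispersion)

    def validate(self) -> None:
        props = self.biotype_proportions
        unknown = set(props) - set(BIOTYPES)
        if unknown:
            raise SimConfigError(f"biotype_proportions: unknown biotypes {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise SimConfigError("biotype_proportions: negative fraction")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise SimConfigError(
                f"biotype_proportions: fractions sum to {sum(props.values())}, expected 1"
            )
        if self.n_hc < 1:
            raise SimConfigError("n_hc: must be >= 1")
        if self.n_patients < 1:
            raise SimConfigError("n_patients: must be >= 1")
        for b in BIOTYPES:
            if self.features_per_biotype(b) < 1:
                raise SimConfigError(f"n_features_per_biotype: must be >= 1 for {b}")
            if self.dispersion_for(b) < 0:
                raise SimConfigError("dispersion: must be >= 0")
            if self.n_planted_per_biotype > self.features_per_biotype(b):
                raise SimConfigError(
                    f"n_planted_per_biotype: exceeds feature count for {b}"
                )
        if not 0.0 <= self.marker_prevalence <= 1.0:
            raise SimConfigError("marker_prevalence: must be in [0, 1]")
        if not 0.0 <= self.postop_residual <= 1.0:
            raise SimConfigError("postop_residual: must be in [0, 1]")
        if not 0.0 <= self.linked_prevalence <= 1.0:
            raise SimConfigError("linked_prevalence: must be in [0, 1]")
        if self.tau_alpha <= 0 or self.tau_beta <= 0:
            raise SimConfigError("tau_alpha/tau_beta: must be > 0")
        if self.lib_size_mean <= 0:
            raise SimConfigError("lib_size_mean: must be > 0")
        if self.marker_mass <= 0 or self.marker_mass >= 1:
            raise SimConfigError("marker_mass: must be in (0, 1)")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise SimConfigError("overlap_fraction: must be in [0, 1]")
        total_planted = self.n_planted_per_biotype * len(BIOTYPES)
        if self.er_linked_markers + self.her2_linked_markers > total_planted:
            raise SimConfigError(
                "er_linked_markers + her2_linked_markers exceed the planted marker count"
            )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator planted: the answer key for recovery tests."""

    planted_markers: set[str]
    carrier_map: dict[str, set[str]]  # patient subject -> planted markers expressed
    tau_values: dict[str, float]  # patient subject -> tumor-EV fraction
    er_linked: set[str] = field(default_factory=set)
    her2_linked: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for subj, markers in self.carrier_map.items():
            if not markers <= self.planted_markers:
                raise ValueError(f"carrier_map[{subj}] not a subset of planted markers")
            if subj not in self.tau_values:
                raise ValueError(f"subject {subj} missing from tau_values")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_markers": sorted(self.planted_markers),
            "carrier_map": {k: sorted(v) for k, v in sorted(self.carrier_map.items())},
            "tau_values": {k: self.tau_values[k] for k in sorted(self.tau_values)},
            "er_linked": sorted(self.er_linked),
            "her2_linked": sorted(self.her2_linked),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_markers=set(d["planted_markers"]),
            carrier_map={k: set(v) for k, v in d["carrier_map"].items()},
            tau_values=d["tau_values"],
            er_linked=set(d.get("er_linked", [])),
            her2_linked=set(d.get("her2_linked", [])),
        )


# ---------------------------------------------------------------------------
# feature bookkeeping


def feature_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic feature roster: id, biotype, planted flag.

    Planted (tumor-specific) features are the last ``n_planted_per_biotype``
    of each biotype and carry ``_planted`` in their id.
    """
    rows = []
    for biotype in BIOTYPES:
        n = config.features_per_biotype(biotype)
        n_planted = config.n_planted_per_biotype
        for i in range(n):
            planted = i >= n - n_planted
            suffix = f"planted{i - (n - n_planted):02d}" if planted else f"{i:04d}"
            rows.append((f"{biotype}_{suffix}", biotype, planted))
    return pd.DataFrame(rows, columns=["feature_id", "biotype", "planted"])


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# toy annotation


def build_toy_annotation(config: SimulationConfig) -> list[FeatureAnnotation]:
    """Lay the feature catalog out on a two-chromosome toy genome.

    A configurable fraction of features is placed overlapping the
    previously placed feature on the same chromosome and strand (when the
    biotypes differ), so that prioritized assignment has real work to do.
    """
    config.validate()
    (rng,) = _rng_streams(config.seed, 3)[:1]
    catalog = feature_catalog(config)
    cursors = {"chr1": 100, "chr2": 100}
    last_on: dict[str, FeatureAnnotation | None] = {"chr1": None, "chr2": None}
    features: list[FeatureAnnotation] = []
    for row in catalog.itertuples(index=False):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        length = int(rng.integers(40, 400))
        prev = last_on[chrom]
        make_overlap = (
            config.overlap_fraction > 0
            and prev is not None
            and prev.biotype != row.biotype
            and rng.random() < config.overlap_fraction
        )
        if make_overlap:
            # start inside the previous feature, guaranteeing >=5 bp overlap
            lo = prev.start
            hi = max(lo + 1, prev.end - 5)
            start = int(rng.integers(lo, hi))
            strand = prev.strand
        else:
            start = cursors[chrom] + int(rng.integers(10, 100))
            strand = "+" if rng.random() < 0.5 else "-"
        feat = FeatureAnnotation(
            feature_id=row.feature_id,
            biotype=row.biotype,
            chrom=chrom,
            start=start,
            end=start + length,
            strand=strand,
            source_db="toy",
        )
        features.append(feat)
        cursors[chrom] = max(cursors[chrom], feat.end)
        last_on[chrom] = feat
    return features


def toy_chrom_sizes(features: Sequence[FeatureAnnotation]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for f in features:
        sizes[f.chrom] = max(sizes.get(f.chrom, 0), f.end + 100)
    return sizes


# ---------------------------------------------------------------------------
# expected proportions of the mixture


def baseline_weights(config: SimulationConfig) -> pd.Series:
    """Per-feature baseline relative abundance (sums to 1).

    Within each biotype, non-planted features get lognormal weights scaled
    to the biotype's share of the read pool; planted (tumor-specific)
    features have zero baseline abundance.
    """
    rng = _rng_streams(config.seed, 3)[1]
    catalog = feature_catalog(config)
    w = np.zeros(len(catalog))
    for biotype in BIOTYPES:
        mask = (catalog["biotype"] == biotype).to_numpy()
        base = mask & ~catalog["planted"].to_numpy()
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=int(base.sum()))
        w[base] = raw / raw.sum() * config.biotype_proportions.get(biotype, 0.0)
    return pd.Series(w / w.sum(), index=catalog["feature_id"].to_numpy())


def tumor_weights(
    config: SimulationConfig, baseline: pd.Series, carried: set[str]
) -> pd.Series:
    """Relative abundance profile of the tumor-derived component.

    Non-planted features keep their baseline proportions re-weighted by the
    per-biotype composition shift; each planted marker the tumor carries
    receives a fixed ``marker_mass`` share of the tumor reads.
    """
    catalog = feature_catalog(config)
    biotype = catalog.set_index("feature_id")["biotype"]
    shift = biotype.map(lambda b: config.composition_shift.get(b, 1.0))
    w = baseline * shift
    carried_mass = config.marker_mass * len(carried)
    if carried_mass >= 1.0:
        raise SimConfigError("marker_mass: carried markers would exceed the read pool")
    w = w / w.sum() * (1.0 - carried_mass)
    for m in carried:
        w[m] = config.marker_mass
    return w


def expected_proportions(
    config: SimulationConfig, tau: float, carried: set[str]
) -> pd.Series:
    """Mixture expectation (1 - tau) * baseline + tau * tumor profile."""
    base = baseline_weights(config)
    if tau == 0.0:
        return base
    return (1.0 - tau) * base + tau * tumor_weights(config, base, carried)


# ---------------------------------------------------------------------------
# clinical covariates


def _assign_categorical(rng: np.random.Generator, n: int, marginal: dict) -> np.ndarray:
    """Assign categories with counts proportional to the marginal (exact at
    the reference n, largest-remainder rounding otherwise), shuffled."""
    cats = list(marginal)
    ref_total = sum(marginal.values())
    raw = [marginal[c] * n / ref_total for c in cats]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw])
    for k in range(rem):
        counts[order[k]] += 1
    values = np.repeat(np.array(cats, dtype=object), counts)
    rng.shuffle(values)
    return values


def sample_clinical(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-patient clinical table with cohort-like marginal frequencies.

    Variables are assigned independently of each other and of the tumor-EV
    fraction; linkage to planted markers is configured separately.
    """
    n = config.n_patients
    subjects = [f"P{i + 1:02d}" for i in range(n)]
    data = {"subject": subjects}
    for var, marginal in CLINICAL_MARGINALS.items():
        data[var] = _assign_categorical(rng, n, marginal)
    return pd.DataFrame(data).set_index("subject")


# ---------------------------------------------------------------------------
# dataset simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion phi) with variance mean + phi * mean^2; Poisson
    where phi == 0."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Draw a full synthetic cohort: counts, sample sheet, ground truth."""
    config.validate()
    _, _, rng = _rng_streams(config.seed, 3)
    catalog = feature_catalog(config)
    feature_ids = catalog["feature_id"].to_numpy()
    biotypes = pd.Series(
        catalog["biotype"].to_numpy(), index=pd.Index(feature_ids, name="feature_id")
    )
    planted = catalog.loc[catalog["planted"], "feature_id"].tolist()
    base = baseline_weights(config).to_numpy()
    phi = biotypes.map(config.dispersion_for).to_numpy()

    subjects = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    hc_ids = [f"HC{i + 1:02d}" for i in range(config.n_hc)]

    clinical = sample_clinical(config, rng)
    tau = rng.beta(config.tau_alpha, config.tau_beta, size=config.n_patients)

    # Carrier map: which planted markers each patient's tumor expresses.
    n_er = config.er_linked_markers
    n_her2 = config.her2_linked_markers
    er_linked = set(planted[:n_er])
    her2_linked = set(planted[n_er : n_er + n_her2])
    carrier_map: dict[str, set[str]] = {}
    for j, subj in enumerate(subjects):
        carried = set()
        er_pos = clinical.loc[subj, "ER"] == "positive"
        her2_pos = clinical.loc[subj, "HER2_IHC"] == 3
        for m in planted:
            if m in er_linked:
                p = config.linked_prevalence if er_pos else 0.0
            elif m in her2_linked:
                p = config.linked_prevalence if her2_pos else 0.0
            else:
                p = config.marker_prevalence
            if rng.random() < p:
                carried.add(m)
        carrier_map[subj] = carried

    subject_effect = {
        s: rng.lognormal(mean=0.0, sigma=config.subject_sd) for s in subjects
    }

    sigma_lib = float(np.sqrt(np.log(1.0 + config.lib_size_cv**2)))
    mu_lib = float(np.log(config.lib_size_mean) - 0.5 * sigma_lib**2)

    base_series = pd.Series(base, index=feature_ids)
    columns: dict[str, np.ndarray] = {}
    rows = []
    for s in hc_ids:
        lib = rng.lognormal(mu_lib, sigma_lib)
        columns[s] = _nb_draw(rng, lib * base, phi)
        rows.append({"sample_id": s, "subject": s, "group": "HC"})
    for j, subj in enumerate(subjects):
        tumor = tumor_weights(config, base_series, carrier_map[subj]).to_numpy()
        for group, tau_eff in (
            ("PreOp", tau[j]),
            ("PostOp", config.postop_residual * tau[j]),
        ):
            p = (1.0 - tau_eff) * base + tau_eff * tumor
            lib = rng.lognormal(mu_lib, sigma_lib)
            sample_id = f"{subj}_{group}"
            columns[sample_id] = _nb_draw(rng, lib * subject_effect[subj] * p, phi)
            row = {"sample_id": sample_id, "subject": subj, "group": group}
            row.update(clinical.loc[subj].to_dict())
            rows.append(row)

    counts = pd.DataFrame(columns, index=pd.Index(feature_ids, name="feature_id"))
    cm = CountMatrix(counts, biotypes)
    samples = SampleTable(pd.DataFrame(rows))
    truth = GroundTruth(
        planted_markers=set(planted),
        carrier_map=carrier_map,
        tau_values={s: float(t) for s, t in zip(subjects, tau)},
        er_linked=er_linked,
        her2_linked=her2_linked,
    )
    truth.validate()
    return cm, samples, truth


# ---------------------------------------------------------------------------
# panel-regime fixture


def simulate_panel_markers(
    seed: int,
    n_cases: int = 32,
    n_controls: int = 30,
    n_informative: int = 8,
    n_noise: int = 42,
    extra_markers_per_case: float = 0.5,
    background_rate: float = 0.0,
    noise_prevalence: float = 0.08,
    abundance_log_mean: float = 7.5,
    abundance_log_sd: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Marker abundance table for panel-model studies, with known truth.

    Emulates a complementary panel of tumor-specific RNAs: each case's
    tumor expresses one informative marker plus ``Poisson(extra)`` further
    ones, drawn without replacement — tumors express subtype-restricted,
    largely non-overlapping marker subsets, so each marker alone has low
    sensitivity (~``(1 + extra)/n_informative``) while the panel jointly
    covers every case.  With ``background_rate=0`` the markers are never
    seen in controls (per-marker specificity 1).  Noise candidates are
    expressed sporadically in cases and controls alike.

    Returns ``(X, y, informative_ids)``: X is samples x markers of
    log1p-transformed abundance, ready for the panel machinery; y is 1 for
    cases.
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    expressed = np.zeros((n, n_informative), dtype=bool)
    for i in range(n_cases):
        k = min(1 + rng.poisson(extra_markers_per_case), n_informative)
        expressed[i, rng.choice(n_informative, size=k, replace=False)] = True
    if background_rate > 0:
        expressed |= rng.random((n, n_informative)) < background_rate
    cols = {}
    informative = [f"marker{j:02d}" for j in range(n_informative)]
    for j, name in enumerate(informative):
        cols[name] = np.where(
            expressed[:, j], rng.lognormal(abundance_log_mean, abundance_log_sd, n), 0.0
        )
    for j in range(n_noise):
        e = rng.random(n) < noise_prevalence
        cols[f"noise{j:02d}"] = np.where(
            e, rng.lognormal(abundance_log_mean, abundance_log_sd, n), 0.0
        )
    X = np.log1p(pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)]))
    return X, y, informative


# ---------------------------------------------------------------------------
# read-level fixture


def _truth_assignment(
    read: AlignmentRecord, annotation: Sequence[FeatureAnnotation]
) -> str | None:
    """Brute-force resolution of the priority rule (scan every feature)."""
    candidates = []
    for f in annotation:
        if f.chrom != read.chrom or f.strand != read.strand:
            continue
        ov = overlap_length(read.start, read.end, f)
        if ov >= 1:
            candidates.append((PRIORITY_ORDER[f.biotype], -ov, f.feature_id))
    if not candidates:
        return None
    return min(candidates)[2]


def simulate_alignments(
    config: SimulationConfig,
    annotation: Sequence[FeatureAnnotation],
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict[str, list[AlignmentRecord]], pd.DataFrame]:
    """Generate per-read alignments from feature bodies plus truth counts.

    Reads are drawn feature-first (feature sampled from the baseline
    composition, read placed uniformly inside the feature body on the
    feature's strand), then each read's truth label is resolved by
    brute-force application of the priority rule — a read landing in an
    overlap region may legitimately belong to a higher-priority neighbor
    rather than the feature that emitted it.

    Returns
    -------
    (alignments_by_sample, truth_counts)
        ``truth_counts`` is a feature x sample DataFrame of the assignments
        a correct prioritized counter must reproduce exactly.
    """
    config.validate()
    if not annotation:
        raise ValueError("annotation is empty")
    rng = _rng_streams(config.seed, 3)[2]
    if sample_ids is None:
        sample_ids = ["S1", "S2"]
    feats = list(annotation)
    base = baseline_weights(config)
    # Restrict to features present in the annotation; planted features have
    # zero baseline mass, so give every feature a floor to exercise them all.
    w = np.array([base.get(f.feature_id, 0.0) + 1e-3 for f in feats])
    w = w / w.sum()
    truth = pd.DataFrame(
        0,
        index=pd.Index([f.feature_id for f in feats], name="feature_id"),
        columns=list(sample_ids),
        dtype=np.int64,
    )
    out: dict[str, list[AlignmentRecord]] = {}
    for s in sample_ids:
        records = []
        choice = rng.choice(len(feats), size=config.n_reads_per_sample, p=w)
        for k, fi in enumerate(choice):
            f = feats[fi]
            rl = min(config.read_length, f.length)
            start = int(rng.integers(f.start, f.end - rl + 1))
            read = AlignmentRecord(
                read_id=f"{s}_r{k:06d}",
                chrom=f.chrom,
                start=start,
                end=start + rl,
                strand=f.strand,
            )
            records.append(read)
            label = _truth_assignment(read, feats)
            if label is not None:
                truth.loc[label, s] += 1
        out[s] = records
    return out, truth
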