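"""Dataset container, similarity curation, stratified splitting and the
applicability domain.

Curation removes molecules whose average Tanimoto similarity to the rest of
the dataset falls below 0.3 — structural singletons that would distort a
single-chemotype QSAR. The train/test split stratifies jointly on activity
quantiles and average similarity so both sets span the same chemistry and
potency range. The applicability domain accepts a query molecule when its
average Tanimoto coefficient against the modelling dataset is at least 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, average_tc, fingerprint, parse_smiles
from .descriptors import DescriptorCalculator

logger = logging.getLogger(__name__)

TC_CURATION_CUTOFF = 0.3
TC_DOMAIN_CUTOFF = 0.5
TRAIN_FRACTION = 0.8


@dataclass
class Dataset:
    """Molecule records with fingerprints and (optionally) descriptors."""

    records: list[MoleculeRecord]
    fingerprints: list = field(default_factory=list)
    descriptors: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.fingerprints:
            self.fingerprints = [fingerprint(parse_smiles(r.smiles))
                                 for r in self.records]
        if len(self.fingerprints) != len(self.records):
            raise ValueError("fingerprint count differs from record count")
        if (self.descriptors is not None
                and len(self.descriptors) != len(self.records)):
            raise ValueError("descriptor rows differ from record count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def activities(self) -> np.ndarray:
        return np.array([np.nan if r.activity is None else r.activity
                         for r in self.records])

    @classmethod
    def from_records(cls, records: list[MoleculeRecord]) -> "Dataset":
        return cls(records=list(records))

    def featurize(self, calculator: DescriptorCalculator | None = None
                  ) -> "Dataset":
        calc = calculator or DescriptorCalculator()
        self.descriptors = calc.fit([]).transform(
            [r.smiles for r in self.records])
        self.descriptors.index = self.ids
        return self

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids,
                           "smiles": [r.smiles for r in self.records],
                           "activity": self.activities})
        if self.descriptors is not None:
            df = pd.concat([df, self.descriptors.reset_index(drop=True)],
                           axis=1)
        return df

    def subset(self, indices) -> "Dataset":
        indices = list(indices)
        return Dataset(
            records=[self.records[i] for i in indices],
            fingerprints=[self.fingerprints[i] for i in indices],
            descriptors=(self.descriptors.iloc[indices]
                         if self.descriptors is not None else None))

    def average_similarities(self) -> np.ndarray:
        """Average Tanimoto of each molecule against the rest."""
        from rdkit import DataStructs
        n = len(self)
        if n < 2:
            return np.ones(n)
        sims = np.zeros((n, n))
        for i in range(n - 1):
            row = DataStructs.BulkTanimotoSimilarity(
                self.fingerprints[i], self.fingerprints[i + 1:])
            sims[i, i + 1:] = row
            sims[i + 1:, i] = row
        return sims.sum(axis=1) / (n - 1)


def curate(dataset: Dataset,
           tc_cutoff: float = TC_CURATION_CUTOFF) -> tuple[Dataset, pd.DataFrame]:
    """Remove molecules with average Tanimoto below ``tc_cutoff``.

    Removal is iterated until every retained molecule has average T_c ≥
    cutoff against the other retained molecules. Returns the curated
    dataset and a log of removals with their average similarities.
    """
    if len(dataset) < 2:
        raise ValueError("curation needs at least 2 molecules")
    kept = list(range(len(dataset)))
    removed: list[tuple[str, float]] = []
    while True:
        sub = dataset.subset(kept)
        avg = sub.average_similarities()
        below = np.flatnonzero(avg < tc_cutoff)
        if below.size == 0:
            break
        for b in below:
            removed.append((sub.ids[b], float(avg[b])))
            logger.info("curation removed %s (average T_c %.3f < %.2f)",
                        sub.ids[b], avg[b], tc_cutoff)
        kept = [k for i, k in enumerate(kept) if i not in set(below.tolist())]
        if not kept:
            raise ValueError(
                f"curation at T_c cutoff {tc_cutoff} removed every molecule")
    log = pd.DataFrame(removed, columns=["id", "average_tc"])
    return dataset.subset(kept), log


@dataclass
class SplitResult:
    train_indices: list[int]
    test_indices: list[int]


def similarity_activity_split(dataset: Dataset,
                              train_fraction: float = TRAIN_FRACTION,
                              seed: int = 0,
                              n_activity_bins: int = 4) -> SplitResult:
    """Stratified train/test split on activity quantiles × similarity halves.

    Strata are the product of activity quartiles and a median split on
    average Tanimoto similarity; each stratum contributes proportionally to
    the test set. The global activity minimum and maximum are forced into
    the training set so test activities always lie inside the training
    range. Deterministic for a fixed seed.
    """
    n = len(dataset)
    if n < 10:
        raise ValueError("need at least 10 molecules to split")
    activities = dataset.activities
    if np.isnan(activities).any():
        raise ValueError("every molecule needs an activity to split on")
    rng = np.random.default_rng(seed)

    strata = _strata(dataset, activities, n_activity_bins)

    n_test_target = n - round(train_fraction * n)
    forced_train = {int(np.argmin(activities)), int(np.argmax(activities))}

    # proportional allocation with largest remainders, honouring forced picks
    groups: dict = {}
    for idx, s in enumerate(strata):
        groups.setdefault(s, []).append(idx)
    quotas = {s: n_test_target * len(m) / n for s, m in groups.items()}
    alloc = {s: int(q) for s, q in quotas.items()}
    shortfall = n_test_target - sum(alloc.values())
    for s in sorted(groups, key=lambda s: quotas[s] - alloc[s], reverse=True):
        if shortfall <= 0:
            break
        alloc[s] += 1
        shortfall -= 1

    test: list[int] = []
    for s, members in sorted(groups.items()):
        eligible = [m for m in members if m not in forced_train]
        k = min(alloc[s], len(eligible))
        if k > 0:
            test.extend(rng.choice(eligible, size=k, replace=False).tolist())
    test_set = set(int(t) for t in test)
    train = [i for i in range(n) if i not in test_set]
    return SplitResult(train_indices=train, test_indices=sorted(test_set))


def _strata(dataset: Dataset, activities: np.ndarray,
            n_activity_bins: int) -> list[tuple[int, int]]:
    try:
        act_bin = pd.qcut(activities, q=n_activity_bins,
                          labels=False, duplicates="drop")
    except ValueError:
        logger.warning("activity quantile binning failed; "
                       "single-stratum fallback")
        act_bin = np.zeros(len(activities), dtype=int)
    try:
        avg_tc = dataset.average_similarities()
        sim_bin = (avg_tc >= np.median(avg_tc)).astype(int)
    except Exception:
        logger.warning("similarity stratification failed; "
                       "activity-only stratification")
        sim_bin = np.zeros(len(activities), dtype=int)
    return [(int(a), int(s)) for a, s in zip(act_bin, sim_bin)]


@dataclass
class DomainVerdict:
    in_domain: bool
    average_tc: float
    cutoff: float


def applicability_domain(record: MoleculeRecord | str, reference: Dataset,
                         cutoff: float = TC_DOMAIN_CUTOFF) -> DomainVerdict:
    """Average-similarity applicability domain check.

    A molecule is in-domain iff its average Tanimoto coefficient against the
    whole modelling dataset is ≥ ``cutoff`` (default 0.5). The average is
    always reported alongside the verdict.
    """
    if len(reference) == 0:
        raise ValueError("empty reference dataset")
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    fp = fingerprint(parse_smiles(smiles))
    avg = average_tc(fp, reference.fingerprints)
    return DomainVerdict(in_domain=avg >= cutoff, average_tc=avg,
                         cutoff=cutoff)
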