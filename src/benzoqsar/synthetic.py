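"""Synthetic benzodiazepine library generator with planted activities.

Emulates a literature-style benzodiazepine structure–activity dataset: four
scaffold families (classic 1,4-benzodiazepin-2-ones, triazolo-, imidazo-
and thieno-triazolo-benzodiazepines) decorated at the positions where real
(designer) benzodiazepines vary — N1 (or the fused-ring methyl), C7 (or the
thiophene 2-position), the pendant-phenyl ortho position C2′, and C3
(hydroxylation, as in oxazepam/lorazepam). Substituents cover H, F, Cl, Br,
NO2, CH3, CF3, NH2 and OH.

Activities are planted by evaluating the published five-descriptor activity
equation on each molecule's own computed descriptors and adding Gaussian
noise, keeping log 1/c inside the experimental span [6.0, 9.0]: molecules
whose noiseless value falls outside are rejected and resampled, and noisy
values are redrawn (truncated noise) or clipped per configuration.

Generation is a pure function of (seed, configuration); the manifest
emitted with every library suffices to regenerate it exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import MoleculeRecord, parse_smiles, write_records_csv, read_csv
from .descriptors import DescriptorCalculator
from .model import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT, \
    PublishedActivityModel

ACTIVITY_RANGE = (6.0, 9.0)
DEFAULT_SIGMA = 0.3


@dataclass(frozen=True)
class ScaffoldTemplate:
    """A scaffold SMILES with named substitution placeholders."""

    name: str
    template: str
    slots: dict[str, tuple[str, ...]]

    def build(self, choice: dict[str, str]) -> str:
        return self.template.format(**choice)

    def combinations(self):
        keys = sorted(self.slots)
        for values in itertools.product(*(self.slots[k] for k in keys)):
            yield dict(zip(keys, values))


_R1 = ("[H]", "C", "CC")                       # N1 / fused-ring alkyl
_R7 = ("[H]", "F", "Cl", "Br", "[N+](=O)[O-]", "C", "C(F)(F)F", "N")
_R2P = ("[H]", "F", "Cl")                      # pendant phenyl ortho
_R3 = ("[H]", "O")                             # C3-H or C3-OH

SCAFFOLDS: tuple[ScaffoldTemplate, ...] = (
    ScaffoldTemplate(
        name="benzodiazepinone_14",
        template="O=C1C({r3})N=C(c2ccccc2{r2p})c2cc({r7})ccc2N1{r1}",
        slots={"r1": _R1, "r7": _R7, "r2p": _R2P, "r3": _R3}),
    ScaffoldTemplate(
        name="triazolo_bzd",
        template="{r1}C1=NN=C2C({r3})N=C(c3ccccc3{r2p})c3cc({r7})ccc3N12",
        slots={"r1": _R1, "r7": _R7, "r2p": _R2P, "r3": _R3}),
    ScaffoldTemplate(
        name="imidazo_bzd",
        template="{r1}C1=NC=C2C({r3})N=C(c3ccccc3{r2p})c3cc({r7})ccc3N12",
        slots={"r1": _R1, "r7": _R7, "r2p": _R2P, "r3": _R3}),
    ScaffoldTemplate(
        name="thieno_triazolo_bzd",
        template="{r1}C1=NN=C2C({r3})N=C(c3ccccc3{r2p})c3cc({r7})sc3N12",
        slots={"r1": _R1, "r7": _R7, "r2p": _R2P, "r3": _R3}),
)


@dataclass
class SyntheticLibrary:
    """Generated molecule records plus the manifest that regenerates them."""

    records: list[MoleculeRecord]
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


_SPACE_CACHE: dict[tuple, dict[str, str]] = {}


def enumerate_unique_space(scaffolds=SCAFFOLDS) -> dict[str, str]:
    """All distinct canonical SMILES reachable from the templates (cached)."""
    key = tuple((s.name, s.template,
                 tuple(sorted((k, v) for k, v in s.slots.items())))
                for s in scaffolds)
    if key not in _SPACE_CACHE:
        seen: dict[str, str] = {}
        for scaffold in scaffolds:
            for choice in scaffold.combinations():
                can = parse_smiles(scaffold.build(choice)).canonical_smiles()
                seen.setdefault(can, scaffold.name)
        _SPACE_CACHE[key] = seen
    return dict(_SPACE_CACHE[key])


def generate_library(n: int, seed: int, scaffolds=SCAFFOLDS,
                     activity_range: tuple[float, float] | None = ACTIVITY_RANGE,
                     max_attempts_factor: int = 200) -> SyntheticLibrary:
    """Draw ``n`` unique benzodiazepine-like molecules by seeded sampling.

    Scaffolds and substituents are sampled uniformly; duplicates (by
    canonical SMILES) are rejected and resampled. When ``activity_range``
    is set, molecules whose noiseless published-equation activity falls
    outside it are rejected too (the literature datasets span exactly that
    range), so every record carries an in-range noiseless activity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = enumerate_unique_space(scaffolds)
    if n > len(space):
        raise ValueError(
            f"requested {n} unique molecules but the template space holds "
            f"only {len(space)}")

    rng = np.random.default_rng(seed)
    calc = DescriptorCalculator(as_frame=False).fit([])
    published = PublishedActivityModel()

    records: list[MoleculeRecord] = []
    noiseless: list[float] = []
    seen: set[str] = set()
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > max_attempts_factor * n:
            raise RuntimeError(
                f"could not draw {n} in-range unique molecules after "
                f"{attempts} attempts; got {len(records)}")
        scaffold = scaffolds[rng.integers(len(scaffolds))]
        choice = {k: scaffold.slots[k][rng.integers(len(scaffold.slots[k]))]
                  for k in sorted(scaffold.slots)}
        can = parse_smiles(scaffold.build(choice)).canonical_smiles()
        if can in seen:
            continue
        value = float(published.predict(calc.transform([can]))[0])
        if activity_range is not None and not \
                (activity_range[0] <= value <= activity_range[1]):
            seen.add(can)   # out-of-range: never acceptable, skip for good
            continue
        seen.add(can)
        records.append(MoleculeRecord(id=f"SYN{len(records):04d}", smiles=can))
        noiseless.append(value)

    manifest = {
        "generator": "benzoqsar.synthetic",
        "n": n, "seed": int(seed),
        "scaffolds": [s.name for s in scaffolds],
        "substituents": {"r1": _R1, "r7": _R7, "r2p": _R2P, "r3": _R3},
        "activity_range": activity_range,
        "planted_intercept": PUBLISHED_INTERCEPT,
        "planted_coefficients": PUBLISHED_COEFFICIENTS,
        "sigma": None,
    }
    lib = SyntheticLibrary(records=records, manifest=manifest)
    lib.manifest["noiseless_activities"] = [round(v, 6) for v in noiseless]
    return lib


def assign_activities(lib: SyntheticLibrary, sigma: float = DEFAULT_SIGMA,
                      seed: int = 0, range_mode: str = "resample",
                      activity_range: tuple[float, float] = ACTIVITY_RANGE,
                      ) -> SyntheticLibrary:
    """Plant activities: published equation on own descriptors + N(0, σ²).

    ``range_mode`` governs noisy values that leave ``activity_range``:
    "resample" redraws the noise (truncated Gaussian, keeps the span
    literal), "clip" clamps to the range edges, "none" leaves them as-is.
    """
    if sigma < 0:
        raise ValueError("noise standard deviation must be >= 0")
    if range_mode not in ("resample", "clip", "none"):
        raise ValueError(f"unknown range_mode {range_mode!r}")
    rng = np.random.default_rng(seed)
    calc = DescriptorCalculator(as_frame=False).fit([])
    published = PublishedActivityModel()
    X = calc.transform([r.smiles for r in lib.records])
    base = published.predict(X)
    lo, hi = activity_range
    for record, mu in zip(lib.records, base):
        value = float(mu)
        if sigma > 0:
            value = float(mu + rng.normal(0.0, sigma))
            if range_mode == "resample":
                guard = 0
                while not (lo <= value <= hi):
                    value = float(mu + rng.normal(0.0, sigma))
                    guard += 1
                    if guard > 1000:
                        value = float(np.clip(value, lo, hi))
                        break
            elif range_mode == "clip":
                value = float(np.clip(value, lo, hi))
        record.activity = value
    lib.manifest.update({"sigma": sigma, "noise_seed": int(seed),
                         "range_mode": range_mode,
                         "activity_range": list(activity_range)})
    return lib


def make_library(n: int, seed: int, sigma: float = DEFAULT_SIGMA,
                 range_mode: str = "resample") -> SyntheticLibrary:
    """Generate and activity-assign a library from a single seed."""
    child = np.random.SeedSequence(seed).spawn(2)
    gen_seed, noise_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                            for c in child)
    lib = generate_library(n, seed=gen_seed)
    return assign_activities(lib, sigma=sigma, seed=noise_seed,
                             range_mode=range_mode)


def regenerate(manifest: dict) -> SyntheticLibrary:
    """Rebuild a library exactly from its manifest."""
    lib = generate_library(manifest["n"], seed=manifest["seed"],
                           activity_range=tuple(manifest["activity_range"])
                           if manifest.get("activity_range") else None)
    if manifest.get("sigma") is not None:
        assign_activities(lib, sigma=manifest["sigma"],
                          seed=manifest["noise_seed"],
                          range_mode=manifest.get("range_mode", "resample"))
    return lib


def write_dataset(lib: SyntheticLibrary, path: str | Path) -> tuple[Path, Path]:
    """Write CSV (id,smiles,activity) plus a manifest JSON sidecar."""
    path = Path(path)
    if any(r.activity is None for r in lib.records):
        raise ValueError("assign activities before writing the dataset")
    write_records_csv(lib.records, path)
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(lib.manifest, indent=2, sort_keys=True))
    return path, manifest_path


def read_dataset(path: str | Path) -> SyntheticLibrary:
    """Round-trip reader for :func:`write_dataset` outputs."""
    path = Path(path)
    records = read_csv(path)
    manifest_path = path.with_suffix(".manifest.json")
    manifest = json.loads(manifest_path.read_text()) \
        if manifest_path.exists() else {}
    return SyntheticLibrary(records=records, manifest=manifest)
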