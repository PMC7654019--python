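"""Synthetic paired datasets with known ground truth.

The generator emulates the simulated person registries used to exercise
linkage engines on Brazilian-style administrative data: random full names
drawn from bundled common-name lists, dates of birth uniform over 1900-2010,
sex uniform on {M, F} and municipality codes in the 7-digit IBGE layout.
A corruption model injects exactly the error types the fuzzy retrieval
targets — single-character typos (including adjacent transpositions),
missing values, middle-name abbreviation and single-digit date errors —
each edit moving a token by exactly one Damerau-Levenshtein unit, so error
counts stay interpretable in edit-distance units.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from . import _names
from .evaluation import GroundTruth
from .schema import AttributeSchema, Dataset, Record

__all__ = [
    "CorruptionConfig",
    "TruthedPair",
    "default_schema",
    "generate_population",
    "corrupt_record",
    "make_truthed_pair",
]

_DOB_START = date(1900, 1, 1)
_DOB_END = date(2010, 12, 31)
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: shared unique key column carried in record extras (drives ground truth)
KEY_COLUMN = "nid"


def default_schema() -> AttributeSchema:
    """The five-attribute linkage schema typical of Brazilian registries.

    Names carry most of the discriminatory power, the birth date some, and
    sex/municipality little; the default weights encode that ordering.
    """
    return AttributeSchema([
        ("name", "string", 5.0),
        ("mother_name", "string", 5.0),
        ("birth_date", "date", 3.0),
        ("sex", "categorical", 1.0),
        ("municipality", "ibge", 1.0),
    ])


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-attribute corruption rates (probabilities in [0, 1]) and the seed."""

    typo_rate: float = 0.0
    transposition_share: float = 0.25
    missing_rate: float = 0.0
    abbreviation_rate: float = 0.0
    date_digit_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("typo_rate", "transposition_share", "missing_rate",
                     "abbreviation_rate", "date_digit_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TruthedPair:
    """Two generated datasets plus the ground truth linking them."""

    dataset_a: Dataset
    dataset_b: Dataset
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        """Write dataset_a.csv, dataset_b.csv and truth.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset_a.to_frame().to_csv(out / "dataset_a.csv", index=False)
        self.dataset_b.to_frame().to_csv(out / "dataset_b.csv", index=False)
        rows = sorted(self.truth.true_pairs)
        with open(out / "truth.csv", "w") as fh:
            fh.write("b_id,a_id\n")
            for b_id, a_id in rows:
                fh.write(f"{b_id},{a_id}\n")


def _random_date(rng: np.random.Generator) -> str:
    span = (_DOB_END - _DOB_START).days
    return (_DOB_START + timedelta(days=int(rng.integers(0, span + 1)))
            ).isoformat()


def _random_person(rng: np.random.Generator) -> dict[str, str]:
    sex = "M" if rng.random() < 0.5 else "F"
    given_pool = _names.MALE_GIVEN if sex == "M" else _names.FEMALE_GIVEN
    given = given_pool[rng.integers(0, len(given_pool))]
    middle = _names.SURNAMES[rng.integers(0, len(_names.SURNAMES))]
    last = _names.SURNAMES[rng.integers(0, len(_names.SURNAMES))]
    m_given = _names.FEMALE_GIVEN[rng.integers(0, len(_names.FEMALE_GIVEN))]
    m_middle = _names.SURNAMES[rng.integers(0, len(_names.SURNAMES))]
    return {
        "name": f"{given} {middle} {last}",
        "mother_name": f"{m_given} {m_middle} {last}",
        "birth_date": _random_date(rng),
        "sex": sex,
        "municipality": _names.IBGE_CODES[
            rng.integers(0, len(_names.IBGE_CODES))],
    }


def generate_population(n: int, seed: int, label: str = "A",
                        id_prefix: str = "A",
                        key_prefix: str = "P") -> Dataset:
    """Generate ``n`` distinct synthetic individuals, deterministic in seed.

    Full-attribute duplicates are rejection-sampled away so every record is
    unique on its complete attribute tuple; each record carries a unique
    national-id-style key in its extras for ground-truth construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    seen: set[tuple[str, ...]] = set()
    i = 0
    while len(records) < n:
        values = _random_person(rng)
        signature = tuple(values.values())
        if signature in seen:
            continue
        seen.add(signature)
        i += 1
        records.append(Record(
            record_id=f"{id_prefix}{i:05d}",
            values=values,
            extras={KEY_COLUMN: f"{key_prefix}{seed}-{i:05d}"},
        ))
    return Dataset(default_schema(), records, label=label)


# -- corruption model ---------------------------------------------------


def _edit_token(token: str, rng: np.random.Generator,
                transposition_share: float) -> str:
    """Apply one random single-character edit (DL distance exactly 1)."""
    if len(token) >= 2 and rng.random() < transposition_share:
        # adjacent transposition of two unequal characters
        positions = [i for i in range(len(token) - 1)
                     if token[i] != token[i + 1]]
        if positions:
            i = positions[rng.integers(0, len(positions))]
            return token[:i] + token[i + 1] + token[i] + token[i + 2:]
    op = rng.integers(0, 3)
    if op == 0 or len(token) < 2:  # substitution
        i = int(rng.integers(0, len(token)))
        choices = _LETTERS.replace(token[i], "")
        return token[:i] + choices[rng.integers(0, len(choices))] + token[i + 1:]
    if op == 1:  # insertion (covers the duplicate-character error)
        i = int(rng.integers(0, len(token) + 1))
        return token[:i] + _LETTERS[rng.integers(0, 26)] + token[i:]
    i = int(rng.integers(0, len(token)))  # deletion
    return token[:i] + token[i + 1:]


def _corrupt_string(value: str, cfg: CorruptionConfig,
                    rng: np.random.Generator) -> str:
    tokens = value.split(" ")
    if len(tokens) >= 3 and rng.random() < cfg.abbreviation_rate:
        tokens[1] = tokens[1][0]
    if rng.random() < cfg.typo_rate:
        editable = [i for i, t in enumerate(tokens) if t]
        i = editable[rng.integers(0, len(editable))]
        tokens[i] = _edit_token(tokens[i], rng, cfg.transposition_share)
    return " ".join(t for t in tokens if t)


def _corrupt_date(value: str, rng: np.random.Generator) -> str:
    digits = value.replace("-", "")
    for _ in range(100):
        pos = int(rng.integers(0, 8))
        new = str(rng.integers(0, 10))
        if new == digits[pos]:
            continue
        cand = digits[:pos] + new + digits[pos + 1:]
        try:
            d = date(int(cand[:4]), int(cand[4:6]), int(cand[6:8]))
        except ValueError:
            continue
        return d.isoformat()
    return value


def corrupt_record(r: Record, cfg: CorruptionConfig,
                   rng: np.random.Generator) -> Record:
    """Return a corrupted copy of a record (id and extras preserved).

    Per attribute: blanking at ``missing_rate``; otherwise string attributes
    get middle-token abbreviation and/or one single-character edit, and date
    attributes a single-digit perturbation that keeps the date a valid
    calendar date.  Categorical and municipality-code attributes are only
    ever blanked.
    """
    values: dict[str, str] = {}
    schema = default_schema()
    for attr in schema:
        v = r.values[attr.name]
        if rng.random() < cfg.missing_rate:
            values[attr.name] = ""
            continue
        if attr.kind == "string" and v:
            v = _corrupt_string(v, cfg, rng)
        elif attr.kind == "date" and v:
            if rng.random() < cfg.date_digit_error_rate:
                v = _corrupt_date(v, rng)
        values[attr.name] = v
    return Record(r.record_id, values, dict(r.extras))


def make_truthed_pair(n_a: int, n_b: int, overlap: float,
                      cfg: CorruptionConfig) -> TruthedPair:
    """Generate linked datasets A (clean) and B (partially corrupted copies).

    ``round(overlap * n_b)`` B records are corrupted copies of distinct A
    records (sharing the unique key, recorded as truth pairs); the rest are
    fresh individuals, rejection-sampled to never coincide with an A record
    on the full attribute tuple.  B is shuffled deterministically.
    """
    if n_b > n_a:
        raise ValueError("n_b must be <= n_a (A is the larger dataset)")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    n_match = round(overlap * n_b)
    if n_match > n_a:
        raise ValueError("overlap implies more matches than A records")

    ss = np.random.SeedSequence(cfg.seed)
    seed_a, seed_fresh, s_pick, s_corrupt, s_shuffle = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5))
    A = generate_population(n_a, seed=seed_a, label="A", id_prefix="A",
                            key_prefix="P")

    rng_pick = np.random.default_rng(s_pick)
    chosen = rng_pick.choice(n_a, size=n_match, replace=False)
    rng_corrupt = np.random.default_rng(s_corrupt)
    b_records: list[Record] = []
    pairs = set()
    for j, idx in enumerate(sorted(int(x) for x in chosen), start=1):
        src = A.records[idx]
        corrupted = corrupt_record(src, cfg, rng_corrupt)
        b_id = f"B{j:05d}"
        b_records.append(Record(b_id, corrupted.values, dict(src.extras)))
        pairs.add((b_id, src.record_id))

    # fresh non-matching individuals, never identical to any A record
    a_signatures = {tuple(r.values[n] for n in A.schema.names) for r in A}
    rng_fresh = np.random.default_rng(seed_fresh)
    j = n_match
    while len(b_records) < n_b:
        values = _random_person(rng_fresh)
        if tuple(values.values()) in a_signatures:
            continue
        j += 1
        b_records.append(Record(
            f"B{j:05d}", values,
            extras={KEY_COLUMN: f"Q{cfg.seed}-{j:05d}"}))

    rng_shuffle = np.random.default_rng(s_shuffle)
    order = rng_shuffle.permutation(len(b_records))
    b_records = [b_records[i] for i in order]
    B = Dataset(default_schema(), b_records, label="B")
    return TruthedPair(A, B, GroundTruth(frozenset(pairs), universe=n_b))
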