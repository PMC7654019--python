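from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from linkcascade import AttributeSchema, Dataset, Record


@pytest.fixture
def schema() -> AttributeSchema:
    """Small mixed-kind schema used across unit tests."""
    return AttributeSchema([
        ("name", "string", 5.0),
        ("mother_name", "string", 5.0),
        ("birth_date", "date", 3.0),
        ("sex", "categorical", 1.0),
        ("municipality", "ibge", 1.0),
    ])


def make_record(rid, name="JOAO DA SILVA", mother="MARIA DA SILVA",
                dob="1990-05-17", sex="M", muni="2927408", **extras):
    return Record(rid, {
        "name": name, "mother_name": mother, "birth_date": dob,
        "sex": sex, "municipality": muni,
    }, dict(extras))


@pytest.fixture
def make_rec():
    return make_record


@pytest.fixture
def small_dataset(schema) -> Dataset:
    records = [
        make_record("a1"),
        make_record("a2", name="MARIA DA SILVA", mother="ANA SOUZA LIMA",
                    dob="1985-01-02", sex="F"),
        make_record("a3", name="JOAO SOUZA", mother="RITA ALVES COSTA",
                    dob="1990-05-17", sex="M", muni="3550308"),
        make_record("a4", name="PEDRO ALMEIDA CRUZ", mother="CLARA NUNES REIS",
                    dob="2001-11-30", sex="M", muni="2910800"),
    ]
    return Dataset(schema, records, label="A")


def random_dataset(schema, n: int, rng: np.random.Generator,
                   prefix: str = "r") -> Dataset:
    """Small random dataset over a deliberately collision-rich vocabulary."""
    givens = ["JOAO", "MARIA", "JOSE", "ANA", "PEDRO", "RITA", "CARLOS"]
    surnames = ["SILVA", "SOUZA", "SANTOS", "LIMA", "COSTA"]
    munis = ["2927408", "2910800", "3550308", "3304557"]
    records = []
    for i in range(n):
        name = " ".join([givens[rng.integers(0, len(givens))],
                         surnames[rng.integers(0, len(surnames))]])
        mother = " ".join([givens[rng.integers(0, len(givens))],
                           surnames[rng.integers(0, len(surnames))]])
        dob = (f"{rng.integers(1950, 2011):04d}-"
               f"{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}")
        rec = Record(f"{prefix}{i:03d}", {
            "name": name, "mother_name": mother, "birth_date": dob,
            "sex": "M" if rng.random() < 0.5 else "F",
            "municipality": munis[rng.integers(0, len(munis))],
        })
        records.append(rec)
    return Dataset(schema, records)
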