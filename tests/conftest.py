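import random

import pytest

from rnamodcensus import (Census, ModificationRecord, build_forest,
                          load_packaged_census)


@pytest.fixture(scope="session")
def census() -> Census:
    return load_packaged_census()


@pytest.fixture(scope="session")
def forest(census):
    return build_forest(census)


def make_record(short, status="placed", root="", parent="", **kw):
    """Terse record constructor for synthetic censuses in tests."""
    return ModificationRecord(
        short_name=short,
        ascii_alias=kw.pop("ascii_alias", short),
        full_name=kw.pop("full_name", f"synthetic {short}"),
        status=status, root_base=root, parent=parent, **kw)


def make_census(records) -> Census:
    return Census(records=tuple(records), version="test", source_note="synthetic")


def random_census(rng: random.Random, n_per_base=12) -> Census:
    """A random but structurally valid synthetic census of placed marks."""
    records = []
    for base in "ACGU":
        names = []
        for i in range(rng.randint(1, n_per_base)):
            name = f"{base.lower()}syn{i}"
            parent = rng.choice(names) if names and rng.random() < 0.6 else ""
            records.append(make_record(name, root=base, parent=parent))
            names.append(name)
    rng.shuffle(records)
    return make_census(records)
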