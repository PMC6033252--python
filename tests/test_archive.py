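"""Chunked archive: storage identities, index-vs-scan equivalence, backends."""

import numpy as np
import pytest

from roipack.archive import Archive, FileBackend, MemoryBackend
from roipack.errors import (
    EmptyCriteriaError,
    KeyConflictError,
    NotFoundError,
)

NAMES = ["AYSE", "MEHMET", "ERDAL", "ATILLA", "FATMA"]
SURNAMES = ["ERDAL", "YILMAZ", "KAYA", "DEMIR"]


def random_patient(rng) -> dict:
    return {
        "name": NAMES[int(rng.integers(len(NAMES)))],
        "surname": SURNAMES[int(rng.integers(len(SURNAMES)))],
        "citizenship_id": str(int(rng.integers(10**9, 2 * 10**9))),
        "study_date": f"20{int(rng.integers(10, 18)):02d}-"
        f"{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}",
    }


def linear_scan(store, **criteria):
    """Brute-force oracle for search_by_criteria."""
    out = []
    for hims_id in store.backend.ids():
        entry = store.search_by_id(hims_id)
        p = entry.patient
        ok = True
        for key in ("name", "surname", "citizenship_id"):
            if criteria.get(key) is not None and p.get(key) != criteria[key]:
                ok = False
        dr = criteria.get("date_range")
        if dr is not None and not (dr[0] <= p.get("study_date", "") < dr[1]):
            ok = False
        if ok:
            out.append(hims_id)
    return sorted(out)


class TestPutGet:
    def test_get_returns_exactly_what_was_put(self):
        store = Archive(chunk_size=64)
        rng = np.random.default_rng(0)
        blob = rng.integers(0, 256, 1000).astype(np.uint8).tobytes()
        store.put(1, random_patient(rng), blob)
        assert store.get(1) == blob

    def test_chunk_count_is_ceil_of_length_over_chunk_size(self):
        store = Archive(chunk_size=256 * 1024)
        entry = store.put(5, {}, b"\x07" * (1024 * 1024))
        assert entry.chunk_count == 4
        rng = np.random.default_rng(1)
        for i, n in enumerate([1, 255, 256, 257, 1000, 64 * 1024]):
            e = Archive(chunk_size=256).put(i, {}, bytes(n))
            assert e.chunk_count == -(-n // 256)

    def test_empty_blob_round_trips_with_zero_chunks(self):
        store = Archive()
        entry = store.put(9, {}, b"")
        assert entry.chunk_count == 0
        assert store.get(9) == b""

    def test_duplicate_key_requires_overwrite(self):
        store = Archive()
        store.put(3, {"name": "A"}, b"x")
        with pytest.raises(KeyConflictError):
            store.put(3, {"name": "B"}, b"y")
        store.put(3, {"name": "B"}, b"y", overwrite=True)
        assert store.get(3) == b"y"
        assert store.search_by_criteria(name="A") == []
        assert store.search_by_criteria(name="B") == [3]

    def test_unknown_id_is_not_found(self):
        with pytest.raises(NotFoundError):
            Archive().get(404)


@pytest.fixture(scope="module")
def seeded():
    rng = np.random.default_rng(2016)
    store = Archive(chunk_size=128)
    for hims_id in rng.permutation(1000):
        store.put(int(hims_id), random_patient(rng), bytes([hims_id % 256]) * 17)
    return store


class TestSearch:
    def test_every_stored_id_resolves_by_primary_key(self, seeded):
        for hims_id in range(1000):
            assert seeded.search_by_id(hims_id).hims_id == hims_id

    def test_criteria_search_matches_the_linear_scan_oracle(self, seeded):
        rng = np.random.default_rng(7)
        for _ in range(60):
            criteria = {}
            if rng.random() < 0.6:
                criteria["name"] = NAMES[int(rng.integers(len(NAMES)))]
            if rng.random() < 0.6:
                criteria["surname"] = SURNAMES[int(rng.integers(len(SURNAMES)))]
            if rng.random() < 0.3:
                y1, y2 = sorted(rng.integers(2010, 2019, 2))
                criteria["date_range"] = (f"{y1}-01-01", f"{y2 + 1}-01-01")
            if not criteria:
                criteria["name"] = "ERDAL"
            got = seeded.search_by_criteria(**criteria)
            assert got == linear_scan(seeded, **criteria)
            assert got == sorted(got)

    def test_date_range_is_half_open(self, seeded):
        lo, hi = "2016-01-01", "2017-01-01"
        ids = seeded.search_by_criteria(date_range=(lo, hi))
        for hims_id in ids:
            assert lo <= seeded.search_by_id(hims_id).patient["study_date"] < hi
        boundary = [
            i for i in range(1000)
            if seeded.search_by_id(i).patient["study_date"] == hi
        ]
        assert not set(boundary) & set(ids)

    def test_impossible_criteria_give_an_empty_list(self, seeded):
        assert seeded.search_by_criteria(name="NOBODY") == []

    def test_empty_criteria_are_refused_by_default(self, seeded):
        with pytest.raises(EmptyCriteriaError):
            seeded.search_by_criteria()
        assert len(seeded.search_by_criteria(allow_full_scan=True)) == 1000


class TestBackends:
    def test_memory_and_file_backends_are_contract_equivalent(self, tmp_path):
        rng = np.random.default_rng(3)
        mem = Archive(MemoryBackend(), chunk_size=200)
        fil = Archive(FileBackend(tmp_path / "store"), chunk_size=200)
        blobs = {}
        for hims_id in range(40):
            patient = random_patient(rng)
            blob = rng.integers(0, 256, int(rng.integers(0, 2000))).astype(
                np.uint8
            ).tobytes()
            blobs[hims_id] = blob
            for store in (mem, fil):
                store.put(hims_id, patient, blob)
        for hims_id, blob in blobs.items():
            assert mem.get(hims_id) == blob == fil.get(hims_id)
            assert mem.search_by_id(hims_id) == fil.search_by_id(hims_id)
        for name in NAMES:
            assert mem.search_by_criteria(name=name) == fil.search_by_criteria(name=name)

    def test_file_backend_survives_reopen(self, tmp_path):
        root = tmp_path / "store"
        Archive(FileBackend(root)).put(11, {"surname": "KAYA"}, b"payload")
        reopened = Archive(FileBackend(root))
        assert reopened.get(11) == b"payload"
        assert reopened.search_by_criteria(surname="KAYA") == [11]
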