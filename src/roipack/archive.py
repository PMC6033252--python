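"""Chunked, indexed archive of packages with a two-mode search engine.

Storage follows the GridFS idea: a *file document* per entry (blob length,
chunk size, chunk count, checksum, patient fields) plus an ordered list of
fixed-size chunks, so blobs far beyond a single-document size limit can be
stored on backends with bounded record sizes.  The default chunk size is
255 KiB, the GridFS convention.

Search is two-mode: ``search_by_id`` resolves the HIMS primary key
directly, while ``search_by_criteria`` conjunctively matches patient
fields (name, surname, citizenship id, half-open study-date range) and
returns the ascending HIMS-ID list; the caller then fetches by id.
Field indexes (hash maps per field, a sorted date list) are maintained on
every put, so criteria search never scans blobs.

Backends are pluggable; the in-memory and file-directory backends below
are contract-equivalent (differentially tested).  The file-directory
layout is one ``meta.json`` plus numbered chunk files per entry.
"""

from __future__ import annotations

import bisect
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

from .errors import (
    ConsistencyError,
    EmptyCriteriaError,
    KeyConflictError,
    NotFoundError,
)

__all__ = [
    "DEFAULT_CHUNK_SIZE",
    "ArchiveEntry",
    "Archive",
    "MemoryBackend",
    "FileBackend",
]

DEFAULT_CHUNK_SIZE = 255 * 1024  # GridFS convention
#: single-document threshold that motivates chunking
DOCUMENT_LIMIT = 16 * 1024 * 1024

PATIENT_FIELDS = ("citizenship_id", "name", "surname", "study_date")


@dataclass(frozen=True)
class ArchiveEntry:
    hims_id: int
    patient: dict[str, str]
    length: int
    chunk_size: int
    chunk_count: int
    checksum: str

    def to_doc(self) -> dict:
        return {
            "hims_id": self.hims_id,
            "patient": dict(self.patient),
            "length": self.length,
            "chunk_size": self.chunk_size,
            "chunk_count": self.chunk_count,
            "checksum": self.checksum,
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "ArchiveEntry":
        return cls(
            hims_id=int(doc["hims_id"]),
            patient=dict(doc["patient"]),
            length=int(doc["length"]),
            chunk_size=int(doc["chunk_size"]),
            chunk_count=int(doc["chunk_count"]),
            checksum=str(doc["checksum"]),
        )


class Backend(Protocol):
    """Minimal storage contract: file documents plus ordered chunks."""

    def ids(self) -> Iterable[int]: ...
    def has(self, hims_id: int) -> bool: ...
    def write_doc(self, hims_id: int, doc: dict) -> None: ...
    def read_doc(self, hims_id: int) -> dict: ...
    def write_chunk(self, hims_id: int, index: int, data: bytes) -> None: ...
    def read_chunk(self, hims_id: int, index: int) -> bytes: ...
    def delete(self, hims_id: int) -> None: ...


class MemoryBackend:
    def __init__(self) -> None:
        self._docs: dict[int, dict] = {}
        self._chunks: dict[tuple[int, int], bytes] = {}

    def ids(self):
        return list(self._docs)

    def has(self, hims_id):
        return hims_id in self._docs

    def write_doc(self, hims_id, doc):
        self._docs[hims_id] = json.loads(json.dumps(doc))

    def read_doc(self, hims_id):
        return self._docs[hims_id]

    def write_chunk(self, hims_id, index, data):
        self._chunks[(hims_id, index)] = bytes(data)

    def read_chunk(self, hims_id, index):
        return self._chunks[(hims_id, index)]

    def delete(self, hims_id):
        doc = self._docs.pop(hims_id)
        for i in range(doc["chunk_count"]):
            self._chunks.pop((hims_id, i), None)


class FileBackend:
    """One directory per entry: ``meta.json`` + ``chunk_<index>.bin``."""

    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _dir(self, hims_id: int) -> Path:
        return self.root / str(int(hims_id))

    def ids(self):
        return [int(p.name) for p in self.root.iterdir()
                if p.is_dir() and p.name.isdigit()]

    def has(self, hims_id):
        return (self._dir(hims_id) / "meta.json").exists()

    def write_doc(self, hims_id, doc):
        d = self._dir(hims_id)
        d.mkdir(exist_ok=True)
        (d / "meta.json").write_text(json.dumps(doc, sort_keys=True))

    def read_doc(self, hims_id):
        return json.loads((self._dir(hims_id) / "meta.json").read_text())

    def write_chunk(self, hims_id, index, data):
        d = self._dir(hims_id)
        d.mkdir(exist_ok=True)
        (d / f"chunk_{index:05d}.bin").write_bytes(data)

    def read_chunk(self, hims_id, index):
        return (self._dir(hims_id) / f"chunk_{index:05d}.bin").read_bytes()

    def delete(self, hims_id):
        d = self._dir(hims_id)
        for p in d.iterdir():
            p.unlink()
        d.rmdir()


class Archive:
    """Keyed blob store with patient-field indexes over a pluggable backend."""

    def __init__(self, backend: Backend | None = None,
                 chunk_size: int = DEFAULT_CHUNK_SIZE) -> None:
        if chunk_size < 1:
            raise ValueError("chunk_size must be positive")
        self.backend = backend if backend is not None else MemoryBackend()
        self.chunk_size = chunk_size
        self._index: dict[str, dict[str, set[int]]] = {
            f: {} for f in ("citizenship_id", "name", "surname")
        }
        self._dates: list[tuple[str, int]] = []
        for hims_id in self.backend.ids():
            self._index_entry(ArchiveEntry.from_doc(self.backend.read_doc(hims_id)))

    # -- indexing ---------------------------------------------------------
    def _index_entry(self, entry: ArchiveEntry) -> None:
        for f in ("citizenship_id", "name", "surname"):
            val = entry.patient.get(f)
            if val is not None:
                self._index[f].setdefault(val, set()).add(entry.hims_id)
        date = entry.patient.get("study_date")
        if date is not None:
            bisect.insort(self._dates, (date, entry.hims_id))

    def _deindex_entry(self, entry: ArchiveEntry) -> None:
        for f in ("citizenship_id", "name", "surname"):
            val = entry.patient.get(f)
            if val is not None:
                self._index[f].get(val, set()).discard(entry.hims_id)
        date = entry.patient.get("study_date")
        if date is not None:
            i = bisect.bisect_left(self._dates, (date, entry.hims_id))
            if i < len(self._dates) and self._dates[i] == (date, entry.hims_id):
                del self._dates[i]

    # -- operations -------------------------------------------------------
    def put(self, hims_id: int, patient: dict[str, str], blob: bytes,
            overwrite: bool = False) -> ArchiveEntry:
        """Chunk and store ``blob`` under ``hims_id``; update all indexes."""
        hims_id = int(hims_id)
        unknown = set(patient) - set(PATIENT_FIELDS)
        if unknown:
            raise ValueError(f"unknown patient fields: {sorted(unknown)}")
        if self.backend.has(hims_id):
            if not overwrite:
                raise KeyConflictError(f"HIMS ID {hims_id} already stored")
            self._deindex_entry(ArchiveEntry.from_doc(self.backend.read_doc(hims_id)))
            self.backend.delete(hims_id)
        chunk_count = -(-len(blob) // self.chunk_size)
        entry = ArchiveEntry(
            hims_id=hims_id,
            patient=dict(patient),
            length=len(blob),
            chunk_size=self.chunk_size,
            chunk_count=chunk_count,
            checksum=hashlib.md5(blob).hexdigest(),
        )
        self.backend.write_doc(hims_id, entry.to_doc())
        for i in range(chunk_count):
            self.backend.write_chunk(
                hims_id, i, blob[i * self.chunk_size : (i + 1) * self.chunk_size]
            )
        self._index_entry(entry)
        return entry

    def get(self, hims_id: int) -> bytes:
        """Reassemble the blob; verifies length and checksum."""
        entry = self.search_by_id(hims_id)
        blob = b"".join(
            self.backend.read_chunk(entry.hims_id, i) for i in range(entry.chunk_count)
        )
        if len(blob) != entry.length:
            raise ConsistencyError(
                f"HIMS ID {hims_id}: reassembled {len(blob)} bytes, expected {entry.length}"
            )
        if hashlib.md5(blob).hexdigest() != entry.checksum:
            raise ConsistencyError(f"HIMS ID {hims_id}: checksum mismatch")
        return blob

    def search_by_id(self, hims_id: int) -> ArchiveEntry:
        hims_id = int(hims_id)
        if not self.backend.has(hims_id):
            raise NotFoundError(f"no entry under HIMS ID {hims_id}")
        return ArchiveEntry.from_doc(self.backend.read_doc(hims_id))

    def search_by_criteria(
        self,
        name: str | None = None,
        surname: str | None = None,
        citizenship_id: str | None = None,
        date_range: tuple[str, str] | None = None,
        allow_full_scan: bool = False,
    ) -> list[int]:
        """Conjunctive criteria search; returns ascending HIMS IDs.

        ``date_range`` is half-open [start, end) on ISO-8601 date strings.
        With no criteria the (unbounded) scan is refused unless
        ``allow_full_scan`` is set.
        """
        criteria_given = any(
            v is not None for v in (name, surname, citizenship_id, date_range)
        )
        if not criteria_given:
            if not allow_full_scan:
                raise EmptyCriteriaError("refusing an unbounded criteria search")
            return sorted(int(i) for i in self.backend.ids())
        result: set[int] | None = None
        for fieldname, value in (
            ("name", name), ("surname", surname), ("citizenship_id", citizenship_id)
        ):
            if value is None:
                continue
            hits = self._index[fieldname].get(value, set())
            result = set(hits) if result is None else result & hits
        if date_range is not None:
            start, end = date_range
            lo = bisect.bisect_left(self._dates, (start, -(1 << 62)))
            hi = bisect.bisect_left(self._dates, (end, -(1 << 62)))
            hits = {i for _, i in self._dates[lo:hi]}
            result = hits if result is None else result & hits
        return sorted(result or set())
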