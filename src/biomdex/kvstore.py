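"""Backend-neutral key-value storage with set algebra.

Everything in the system — inverted indices, sparse sample vectors,
metadata records, stem indices, registries — is expressed against this
small contract: string values, field->value records, and string sets with
intersection / union / difference.  The contract is deliberately minimal
(no key-pattern scanning, no transactions) so that it can be implemented on
any key-value engine; enumerable collections are maintained as explicit
registry sets by the layers above.

Keys are composite ``namespace:category:item`` triples.  The rendered form
must be injective, so no component may contain the ``:`` separator; this is
enforced at write time.

:class:`MemoryStore` is the reference implementation: in-process dicts with
explicit snapshot save/load to a single versioned file.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

SEPARATOR = ":"

#: magic first line of a snapshot file; the trailing integer is the format
#: version and is checked on load.
SNAPSHOT_MAGIC = "#biomdex-snapshot 1"


class StoreError(Exception):
    """Base class for storage-contract violations."""


class InvalidKeyError(StoreError):
    """A key component contains the separator or is otherwise malformed."""


@dataclass(frozen=True)
class StoreKey:
    """Composite storage key rendered as ``namespace:category:item``."""

    namespace: str
    category: str
    item: str

    def validate(self) -> None:
        for part_name in ("namespace", "category", "item"):
            part = getattr(self, part_name)
            if SEPARATOR in part:
                raise InvalidKeyError(
                    f"key {part_name} {part!r} contains the reserved "
                    f"separator {SEPARATOR!r}"
                )

    def render(self) -> str:
        self.validate()
        return SEPARATOR.join((self.namespace, self.category, self.item))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


class KeyValueBackend(ABC):
    """Contract for string / record / set storage with set algebra.

    Implementations must keep the three storage kinds independent per key
    and must never let operations on one namespace affect another.  All
    returned collections are in lexicographic order wherever order is
    observable.
    """

    # -- string values ----------------------------------------------------
    @abstractmethod
    def put_value(self, key: StoreKey, value: str) -> None:
        """Associate ``key`` with ``value``, silently overwriting."""

    @abstractmethod
    def get_value(self, key: StoreKey) -> str | None:
        """Return the stored value, or ``None`` if the key is absent."""

    @abstractmethod
    def delete_value(self, key: StoreKey) -> bool:
        """Remove a string value; return whether it existed."""

    # -- sets ---------------------------------------------------------------
    @abstractmethod
    def set_add(self, key: StoreKey, members: Iterable[str]) -> int:
        """Add members (union semantics); return the number newly added."""

    @abstractmethod
    def set_members(self, key: StoreKey) -> set[str]:
        """Return the set under ``key``; absent keys are the empty set."""

    def set_combine(
        self, keys: Sequence[StoreKey], mode: str = "intersection"
    ) -> set[str]:
        """Combine the sets under ``keys``.

        ``mode`` is one of ``intersection``, ``union`` or ``difference``;
        difference is a left fold (first set minus all the rest).
        """
        if not keys:
            raise StoreError("set_combine requires at least one key")
        sets = [self.set_members(k) for k in keys]
        if mode == "intersection":
            out = sets[0].copy()
            for s in sets[1:]:
                out &= s
        elif mode == "union":
            out = set()
            for s in sets:
                out |= s
        elif mode == "difference":
            out = sets[0].copy()
            for s in sets[1:]:
                out -= s
        else:
            raise StoreError(f"unknown set_combine mode {mode!r}")
        return out

    # -- records ------------------------------------------------------------
    @abstractmethod
    def record_put(self, key: StoreKey, fields: Mapping[str, str]) -> None:
        """Merge ``fields`` into the record under ``key``."""

    @abstractmethod
    def record_get(
        self, key: StoreKey, fields: Sequence[str] | None = None
    ) -> dict[str, str | None]:
        """Return the requested fields (all when ``fields`` is None).

        Missing fields map to ``None``; requesting all fields of an absent
        key returns an empty dict.
        """

    @abstractmethod
    def record_delete_fields(self, key: StoreKey, fields: Sequence[str]) -> int:
        """Remove fields from a record; return how many existed."""


class MemoryStore(KeyValueBackend):
    """In-memory reference backend with snapshot persistence.

    Small sets and records are held as plain Python containers; a compact
    encoding of small collections is an internal representation concern and
    is not observable through the contract.
    """

    def __init__(self) -> None:
        self._values: dict[str, str] = {}
        self._sets: dict[str, set[str]] = {}
        self._records: dict[str, dict[str, str]] = {}

    # -- string values ----------------------------------------------------
    def put_value(self, key: StoreKey, value: str) -> None:
        self._values[key.render()] = str(value)

    def get_value(self, key: StoreKey) -> str | None:
        return self._values.get(key.render())

    def delete_value(self, key: StoreKey) -> bool:
        return self._values.pop(key.render(), None) is not None

    # -- sets ---------------------------------------------------------------
    def set_add(self, key: StoreKey, members: Iterable[str]) -> int:
        target = self._sets.setdefault(key.render(), set())
        before = len(target)
        target.update(str(m) for m in members)
        return len(target) - before

    def set_members(self, key: StoreKey) -> set[str]:
        return set(self._sets.get(key.render(), ()))

    def set_remove(self, key: StoreKey, members: Iterable[str]) -> int:
        rendered = key.render()
        target = self._sets.get(rendered)
        if target is None:
            return 0
        before = len(target)
        target.difference_update(members)
        if not target:
            del self._sets[rendered]
        return before - len(target)

    # -- records ------------------------------------------------------------
    def record_put(self, key: StoreKey, fields: Mapping[str, str]) -> None:
        key.validate()
        if fields:
            target = self._records.setdefault(key.render(), {})
            for name, value in fields.items():
                target[str(name)] = str(value)

    def record_get(
        self, key: StoreKey, fields: Sequence[str] | None = None
    ) -> dict[str, str | None]:
        record = self._records.get(key.render(), {})
        if fields is None:
            return dict(sorted(record.items()))
        return {name: record.get(name) for name in fields}

    def record_delete_fields(self, key: StoreKey, fields: Sequence[str]) -> int:
        rendered = key.render()
        record = self._records.get(rendered)
        if record is None:
            return 0
        removed = 0
        for name in fields:
            if name in record:
                del record[name]
                removed += 1
        if not record:
            del self._records[rendered]
        return removed

    # -- snapshots ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the full store to a single self-describing snapshot file."""
        payload = {
            "values": dict(sorted(self._values.items())),
            "sets": {k: sorted(v) for k, v in sorted(self._sets.items())},
            "records": {
                k: dict(sorted(v.items()))
                for k, v in sorted(self._records.items())
            },
        }
        text = SNAPSHOT_MAGIC + "\n" + json.dumps(
            payload, sort_keys=True, separators=(",", ":")
        )
        Path(path).write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "MemoryStore":
        """Load a snapshot written by :meth:`save`."""
        text = Path(path).read_text(encoding="utf-8")
        header, _, body = text.partition("\n")
        if header != SNAPSHOT_MAGIC:
            raise StoreError(
                f"not a recognised snapshot file (header {header!r})"
            )
        payload = json.loads(body)
        store = cls()
        store._values = dict(payload["values"])
        store._sets = {k: set(v) for k, v in payload["sets"].items()}
        store._records = {k: dict(v) for k, v in payload["records"].items()}
        return store
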