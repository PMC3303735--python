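"""Specimen anonymization: barcode payloads and the segregated lookup table.

Each consented biospecimen is labelled with the textual payload of a 2-D
DataMatrix barcode that carries no reference to the donor.  The payload is

    FSM-BB-XXX-XXX-XXX-XC

ten random characters from the Crockford base-32 alphabet (no I, L, O, U —
unambiguous when printed on a frozen vial) plus one mod-37 check character,
grouped so that no run of four consecutive symbols occurs; a length-4
substring of a personal name therefore can never appear in a payload.

The payload <-> donor relation lives only in a :class:`LookupTable`, kept
in its own store physically separate from warehouse and biobank exports;
resolution back to the pathology-unit patient id is gated by an explicit
authorization flag.  Rendering the actual 2-D barcode image is out of
scope — the payload string is the artifact.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "BarcodePayload",
    "LookupTable",
    "AuthorizationError",
    "LinkConflictError",
    "PayloadNotFoundError",
    "CapacityError",
    "PAYLOAD_PREFIX",
    "PAYLOAD_RE",
    "new_barcode",
    "verify_payload",
    "assert_no_phi",
]

PAYLOAD_PREFIX = "FSM-BB-"
ALPHABET = "0123456789ABCDEFGHJKMNPQRSTVWXYZ"  # Crockford base-32
CHECK_ALPHABET = ALPHABET + "*~$=U"  # mod-37 check symbols
_GROUPS = (3, 3, 3)  # data grouping; final group = 1 data char + check char
N_DATA_CHARS = 10

PAYLOAD_RE = re.compile(
    r"^FSM-BB-[0-9A-HJKMNP-TV-Z]{3}-[0-9A-HJKMNP-TV-Z]{3}"
    r"-[0-9A-HJKMNP-TV-Z]{3}-[0-9A-HJKMNP-TV-Z][0-9A-HJKMNP-TV-Z*~$=U]$"
)


class AuthorizationError(PermissionError):
    """Lookup resolution attempted without authorization."""


class LinkConflictError(ValueError):
    """Payload already linked to a different patient."""


class PayloadNotFoundError(KeyError):
    """Payload has no entry in the lookup table."""


class CapacityError(RuntimeError):
    """The payload space is (practically) exhausted."""


def _check_char(data: str) -> str:
    value = 0
    for ch in data:
        value = value * 32 + ALPHABET.index(ch)
    return CHECK_ALPHABET[value % 37]


def _format_payload(data: str) -> str:
    a, b, c = (data[0:3], data[3:6], data[6:9])
    tail = data[9] + _check_char(data)
    return f"{PAYLOAD_PREFIX}{a}-{b}-{c}-{tail}"


@dataclass(frozen=True)
class BarcodePayload:
    payload: str

    def __post_init__(self):
        if not verify_payload(self.payload):
            raise ValueError(f"invalid barcode payload: {self.payload!r}")

    def __str__(self) -> str:
        return self.payload


def verify_payload(payload: str) -> bool:
    """Format and check-character verification."""
    if not PAYLOAD_RE.match(payload):
        return False
    body = payload[len(PAYLOAD_PREFIX):].replace("-", "")
    data, check = body[:N_DATA_CHARS], body[N_DATA_CHARS]
    return _check_char(data) == check


@dataclass
class LookupTable:
    """Bidirectional payload <-> pathology-unit patient id map.

    One payload maps to exactly one patient; a patient may hold many
    payloads (one per aliquot).  Persisted in its own directory, never
    alongside warehouse or biobank exports.
    """

    by_payload: dict[str, str] = field(default_factory=dict)
    by_patient: dict[str, set[str]] = field(default_factory=dict)

    def link(self, pu_patient_id: str, payload: str | BarcodePayload) -> None:
        payload = str(payload)
        existing = self.by_payload.get(payload)
        if existing is not None:
            if existing != pu_patient_id:
                raise LinkConflictError(
                    f"payload {payload} already linked to a different patient"
                )
            return  # relink of the same pair is a no-op
        self.by_payload[payload] = pu_patient_id
        self.by_patient.setdefault(pu_patient_id, set()).add(payload)

    def resolve(self, payload: str | BarcodePayload, authorized: bool = False) -> str:
        if not authorized:
            raise AuthorizationError("lookup resolution requires authorization")
        payload = str(payload)
        try:
            return self.by_payload[payload]
        except KeyError:
            raise PayloadNotFoundError(payload) from None

    def payloads(self) -> set[str]:
        return set(self.by_payload)

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "lookup.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("payload\tpu_patient_id\n")
            for payload in sorted(self.by_payload):
                fh.write(f"{payload}\t{self.by_payload[payload]}\n")
        return path

    @classmethod
    def load(cls, directory: str | Path) -> "LookupTable":
        path = Path(directory) / "lookup.tsv"
        table = cls()
        with path.open(encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "payload\tpu_patient_id":
                raise ValueError(f"unexpected lookup header: {header!r}")
            for line in fh:
                payload, pu_id = line.rstrip("\n").split("\t")
                table.link(pu_id, payload)
        return table


def new_barcode(lookup: LookupTable, rng: random.Random,
                max_attempts: int = 1000) -> BarcodePayload:
    """Draw a fresh payload, unique with respect to ``lookup``.

    Generation from a seeded ``random.Random`` is reproducible.
    """
    known = lookup.by_payload
    for _ in range(max_attempts):
        data = "".join(rng.choice(ALPHABET) for _ in range(N_DATA_CHARS))
        payload = _format_payload(data)
        if payload not in known:
            return BarcodePayload(payload)
    raise CapacityError("could not draw an unused payload")


def assert_no_phi(payload: str | BarcodePayload, patient_fields: list[str],
                  min_len: int = 4) -> bool:
    """True iff no case-normalized substring (length >= ``min_len``) of any
    patient identifier field occurs in the payload.

    Checking windows of exactly ``min_len`` suffices: any longer leaked
    substring contains one.
    """
    hay = str(payload).upper()
    for fld in patient_fields:
        norm = str(fld).upper()
        for i in range(len(norm) - min_len + 1):
            if norm[i:i + min_len] in hay:
                return False
    return True
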