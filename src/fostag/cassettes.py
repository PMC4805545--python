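"""Tag-cassette registry.

A tag cassette is an ordered list of (role, sequence) segments: epitope
linkers, a fluorophore, auxiliary epitopes, and an FRT-flanked
selection/counter-selection operon that is excised in vivo by Flp
recombinase ("flip-out"), leaving a single in-frame FRT scar.  The
registry shipped with the package contains synthetic stand-in sequences
with the structural properties of real cassettes (segment lengths a
multiple of three where they code, a 34-nt FRT, a sfGFP-sized fluorophore);
users can point the loader at their own YAML with real sequences.

The pre-tagging cassette is a selectable placeholder whose flanks are the
first and last epitope segments of every tag cassette, which makes the
second tagging step a universal cassette exchange.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from ._util import has_inframe_stop

VALID_ROLES = {"linker-epitope", "fluorophore", "epitope", "protease-site",
               "blrp", "frt", "selection-marker", "stop-free-spacer"}


@dataclass(frozen=True)
class TagCassette:
    name: str
    segments: tuple[tuple[str, str], ...]  # (role, sequence), 5'->3'

    def __post_init__(self):
        bad = {r for r, _ in self.segments} - VALID_ROLES
        if bad:
            raise ValueError(f"{self.name}: unknown segment roles {bad}")
        if sum(1 for r, _ in self.segments if r == "frt") != 2:
            raise ValueError(f"{self.name}: cassette must carry exactly two FRT sites")

    @property
    def unflipped_form(self) -> str:
        """Full cassette with the FRT-flanked selection operon present."""
        return "".join(seq for _, seq in self.segments)

    @property
    def flipped_form(self) -> str:
        """Cassette after Flp excision: one FRT remains, marker gone."""
        frt_idx = [i for i, (r, _) in enumerate(self.segments) if r == "frt"]
        i, j = frt_idx
        parts = [seq for _, seq in self.segments[:i + 1]]  # keep first FRT
        parts += [seq for _, seq in self.segments[j + 1:]]
        return "".join(parts)

    @property
    def frt(self) -> str:
        return next(seq for r, seq in self.segments if r == "frt")

    @property
    def marker(self) -> str:
        return next(seq for r, seq in self.segments if r == "selection-marker")

    @property
    def flank5(self) -> str:
        return self.segments[0][1]

    @property
    def flank3(self) -> str:
        return self.segments[-1][1]

    def validate(self) -> None:
        """Frame/stop/FRT invariants of the flipped form."""
        f = self.flipped_form
        if len(f) % 3 != 0:
            raise ValueError(f"{self.name}: flipped form length {len(f)} not % 3")
        if has_inframe_stop(f):
            raise ValueError(f"{self.name}: flipped form has an in-frame stop")
        if f.count(self.frt) != 1:
            raise ValueError(f"{self.name}: flipped form must contain exactly one FRT")


@dataclass(frozen=True)
class PreTagCassette:
    """Selectable placeholder: marker flanked by the universal linker epitopes."""

    marker: str
    flank5: str
    flank3: str

    @property
    def sequence(self) -> str:
        return self.flank5 + self.marker + self.flank3


def load_registry(path: str | None = None) -> dict:
    """Load cassette definitions from YAML (package default if path is None).

    Returns ``{"tags": {name: TagCassette}, "pretag": PreTagCassette}``;
    every tag cassette is validated on load and the pre-tag flanks are
    checked against every tag's terminal segments.
    """
    if path is None:
        text = (importlib.resources.files("fostag") / "data" / "cassettes.yaml"
                ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tags = {}
    pre_raw = raw.pop("pretag")
    for name, entry in raw.items():
        cas = TagCassette(name, tuple((r, s) for r, s in entry["segments"]))
        cas.validate()
        tags[name] = cas
    any_tag = next(iter(tags.values()))
    pretag = PreTagCassette(pre_raw["marker"], any_tag.flank5, any_tag.flank3)
    for cas in tags.values():
        if cas.flank5 != pretag.flank5 or cas.flank3 != pretag.flank3:
            raise ValueError(
                f"{cas.name}: terminal segments differ from the pre-tag flanks; "
                "cassette exchange would not be universal")
    return {"tags": tags, "pretag": pretag}
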