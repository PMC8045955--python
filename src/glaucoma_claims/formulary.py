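"""Ophthalmic drug taxonomy: products, classes, and regimen classification.

Topical IOP-lowering drugs are grouped into pharmacological classes
(prostaglandin analogs, beta blockers, carbonic anhydrase inhibitors, ...).
A *fixed combination* is a single bottle containing two classes; an
*unfixed combination* is the same classes dispensed as separate bottles.
Bottle volume follows the Japanese convention: 2.5 mL for once-daily
formulations, 5 mL for twice-or-more-daily ones, and either volume covers
one eye for 30 dispensed days.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

#: Allowed drug-class codes: prostaglandin analog, beta blocker, carbonic
#: anhydrase inhibitor, alpha-2 agonist, alpha-1 blocker, alpha-beta blocker,
#: cholinergic agonist, muscarinic agonist, rho-kinase inhibitor.
DRUG_CLASSES = frozenset(
    {"PG", "BB", "CAI", "AA", "AB", "ABB", "CHOL", "MA", "ROCKI"}
)


class DosingFrequency(str, enum.Enum):
    ONCE_DAILY = "ONCE_DAILY"
    MULTI_DAILY = "MULTI_DAILY"


class Regimen(str, enum.Enum):
    """Same-day regimen category of one patient's dispensings."""

    MONO = "MONO"
    FIXED = "FIXED"
    UNFIXED = "UNFIXED"


class FormularyError(ValueError):
    """Raised for malformed formulary rows or unresolvable product codes."""


_VOLUME_BY_FREQUENCY = {
    DosingFrequency.ONCE_DAILY: 2.5,
    DosingFrequency.MULTI_DAILY: 5.0,
}


@dataclass(frozen=True)
class DrugProduct:
    """One marketed eye-drop product.

    ``drug_classes`` holds one class for a monotherapy product and two or
    more for a fixed combination; ``is_fixed_combination`` must agree.
    """

    product_code: str
    generic_name: str
    drug_classes: frozenset[str]
    is_fixed_combination: bool
    bottle_volume_ml: float
    dosing_frequency: DosingFrequency
    is_generic: bool = False

    def __post_init__(self) -> None:
        unknown = self.drug_classes - DRUG_CLASSES
        if unknown:
            raise FormularyError(
                f"{self.product_code}: unknown drug class code(s) {sorted(unknown)}"
            )
        if not self.drug_classes:
            raise FormularyError(f"{self.product_code}: empty drug class set")
        if self.is_fixed_combination != (len(self.drug_classes) >= 2):
            raise FormularyError(
                f"{self.product_code}: is_fixed_combination={self.is_fixed_combination} "
                f"inconsistent with {len(self.drug_classes)} drug class(es)"
            )
        if self.bottle_volume_ml not in (2.5, 5.0):
            raise FormularyError(
                f"{self.product_code}: bottle volume must be 2.5 or 5.0 mL, "
                f"got {self.bottle_volume_ml}"
            )
        if _VOLUME_BY_FREQUENCY[self.dosing_frequency] != self.bottle_volume_ml:
            raise FormularyError(
                f"{self.product_code}: {self.dosing_frequency.value} products "
                f"use {_VOLUME_BY_FREQUENCY[self.dosing_frequency]} mL bottles, "
                f"got {self.bottle_volume_ml}"
            )


@dataclass
class Formulary:
    """Lookup from product code to :class:`DrugProduct`."""

    products: dict[str, DrugProduct] = field(default_factory=dict)

    def __getitem__(self, product_code: str) -> DrugProduct:
        try:
            return self.products[product_code]
        except KeyError:
            raise FormularyError(
                f"product code {product_code!r} not in formulary"
            ) from None

    def __contains__(self, product_code: str) -> bool:
        return product_code in self.products

    def __len__(self) -> int:
        return len(self.products)

    def add(self, product: DrugProduct) -> None:
        if product.product_code in self.products:
            raise FormularyError(f"duplicate product code {product.product_code!r}")
        self.products[product.product_code] = product

    def codes(self) -> list[str]:
        return list(self.products)


_FIELDS = (
    "product_code",
    "generic_name",
    "drug_classes",
    "is_fixed_combination",
    "bottle_volume_ml",
    "dosing_frequency",
    "is_generic",
)

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_row(row: Mapping[str, str], lineno: int) -> DrugProduct:
    try:
        return DrugProduct(
            product_code=row["product_code"].strip(),
            generic_name=row["generic_name"].strip(),
            drug_classes=frozenset(
                c.strip() for c in row["drug_classes"].split("|") if c.strip()
            ),
            is_fixed_combination=_BOOL[row["is_fixed_combination"].strip().lower()],
            bottle_volume_ml=float(row["bottle_volume_ml"]),
            dosing_frequency=DosingFrequency(row["dosing_frequency"].strip()),
            is_generic=_BOOL[row["is_generic"].strip().lower()],
        )
    except FormularyError as exc:
        raise FormularyError(f"formulary row {lineno}: {exc}") from None
    except (KeyError, ValueError) as exc:
        raise FormularyError(f"formulary row {lineno}: malformed ({exc})") from None


def load_formulary(path: str | Path) -> Formulary:
    """Read a formulary CSV and return a validated :class:`Formulary`.

    Columns: product_code, generic_name, drug_classes (pipe-separated),
    is_fixed_combination, bottle_volume_ml, dosing_frequency, is_generic.
    Rejects unknown class codes, duplicate product codes, and
    volume/frequency inconsistencies, naming the offending row.
    """
    formulary = Formulary()
    with open(path, newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        missing = set(_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise FormularyError(f"formulary missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            product = _parse_row(row, lineno)
            try:
                formulary.add(product)
            except FormularyError as exc:
                raise FormularyError(f"formulary row {lineno}: {exc}") from None
    if not formulary.products:
        raise FormularyError(f"formulary at {path} has no products")
    return formulary


def default_formulary() -> Formulary:
    """The formulary shipped with the package.

    Covers the generics that dominate Japanese first-line glaucoma therapy:
    the common prostaglandin monotherapies, beta blockers, and the marketed
    fixed combinations (e.g. latanoprost/timolol, dorzolamide/timolol).
    """
    ref = resources.files("glaucoma_claims.data").joinpath("default_formulary.csv")
    with resources.as_file(ref) as path:
        return load_formulary(path)


def classify_regimen(products_on_day: Iterable[DrugProduct]) -> Regimen:
    """Classify one patient's same-day dispensings as MONO, FIXED or UNFIXED.

    Exactly one non-combination product is a monotherapy; exactly one
    fixed-combination product is a fixed combination; two or more distinct
    products on the same day are an unfixed combination, whatever their
    classes.
    """
    products = {p.product_code: p for p in products_on_day}
    if not products:
        raise ValueError("classify_regimen requires at least one product")
    if len(products) >= 2:
        return Regimen.UNFIXED
    (product,) = products.values()
    return Regimen.FIXED if product.is_fixed_combination else Regimen.MONO
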