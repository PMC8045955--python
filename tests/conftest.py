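from __future__ import annotations

from datetime import date, timedelta

import pytest

from glaucoma_claims.adherence import PharmacyClaim
from glaucoma_claims.formulary import default_formulary

BASE_DATE = date(2013, 4, 1)


@pytest.fixture(scope="session")
def formulary():
    return default_formulary()


def make_claim(
    rel_day: int,
    n_bottles: int = 1,
    product_code: str = "LAT01",
    bottle_ml: float = 2.5,
    patient_id: str = "P1",
) -> PharmacyClaim:
    """A claim ``rel_day`` days after the session base date."""
    return PharmacyClaim(
        patient_id=patient_id,
        dispense_date=BASE_DATE + timedelta(days=rel_day),
        product_code=product_code,
        quantity_ml=n_bottles * bottle_ml,
        period_field="1",
    )


def make_claims(day_bottles, **kwargs):
    return [make_claim(d, b, **kwargs) for d, b in day_bottles]
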