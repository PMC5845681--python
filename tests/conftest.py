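import pytest

from gaitkit.core import PawContact, PawLabel, Run
from gaitkit.synth import PhenotypeParams, generate_run


@pytest.fixture
def oracle_run():
    """Noiseless crossing at v=35 cm/s, L=14 cm, d=0.55, default phases."""
    run, truth = generate_run(v=35.0, L=14.0, d=0.55)
    return run, truth


@pytest.fixture
def default_params():
    return PhenotypeParams()


def make_run(contacts, *, t_exit=None, walkway=70.0, interrupted=False, week=1):
    """Small hand-built run; t_exit defaults to just past the last lift-off."""
    if t_exit is None:
        t_exit = max(c.t_liftoff for c in contacts) + 0.01
    return Run(
        animal_id="a00",
        group="sham_mfb",
        week=week,
        run_id="r0",
        walkway_length=walkway,
        t_enter=0.0,
        t_exit=t_exit,
        contacts=list(contacts),
        interrupted=interrupted,
    )


def contact(paw, t_on, t_off, x, y=0.0, length=2.0, area=1.5, series=None):
    return PawContact(
        paw=paw if isinstance(paw, PawLabel) else PawLabel(paw),
        t_contact=t_on,
        t_liftoff=t_off,
        x=x,
        y=y,
        print_length=length,
        print_area=area,
        area_series=series,
    )
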