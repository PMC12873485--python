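import itertools

import pytest
from hypothesis import settings

from npiscore import NutrientProfile

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

# Independent re-statement of the 2004/05 threshold tables, used by the
# brute-force oracle below. Deliberately typed out again rather than read
# from the package so the oracle does not share the implementation's path.
ORACLE_A = {
    "energy": [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350],
    "satfat": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
    "sugar": [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45],
    "sodium": [90, 180, 270, 360, 450, 540, 630, 720, 810, 900],
}
ORACLE_FVN = [(40, 1), (60, 2), (80, 5)]
ORACLE_FIBRE = {
    "NSP": [0.7, 1.4, 2.1, 2.8, 3.5],
    "AOAC": [0.9, 1.9, 2.8, 3.7, 4.7],
}
ORACLE_PROTEIN = [1.6, 3.2, 4.8, 6.4, 8.0]


def oracle_table_points(table, amount):
    """Scan from the top bin down; first threshold strictly exceeded wins."""
    for n in range(len(table), 0, -1):
        if amount > table[n - 1]:
            return n
    return 0


def oracle_fvn_points(pct):
    points = 0
    for threshold, pts in ORACLE_FVN:
        if pct > threshold:
            points = pts
    return points


def oracle_npm_total(profile: NutrientProfile) -> int:
    """Brute-force NPM total straight from the rule statement."""
    a = (oracle_table_points(ORACLE_A["energy"], profile.energy_kj)
         + oracle_table_points(ORACLE_A["satfat"], profile.satfat_g)
         + oracle_table_points(ORACLE_A["sugar"], profile.sugar_g)
         + oracle_table_points(ORACLE_A["sodium"], profile.sodium_mg))
    c_fvn = oracle_fvn_points(profile.fvn_pct or 0.0)
    c_fibre = oracle_table_points(ORACLE_FIBRE[profile.fibre_basis], profile.fibre_g or 0.0)
    c_protein = oracle_table_points(ORACLE_PROTEIN, profile.protein_g or 0.0)
    if a >= 11 and c_fvn < 5:
        c_protein = 0
    return a - c_fvn - c_fibre - c_protein


def boundary_straddling_profiles(eps=0.05):
    """Profiles with every A-nutrient at a threshold +/- eps; C-components
    cycle over their own boundary-straddling values. > 10 000 profiles."""
    def straddle(table):
        return [t - eps for t in table] + [t + eps for t in table]

    energies = [0.0] + straddle(ORACLE_A["energy"])
    satfats = [0.0] + straddle(ORACLE_A["satfat"])
    sugars = [0.0] + straddle(ORACLE_A["sugar"])
    sodiums = [0.0] + straddle(ORACLE_A["sodium"])
    fvns = [0.0] + [t - eps for t, _ in ORACLE_FVN] + [t + eps for t, _ in ORACLE_FVN]
    fibres = [0.0] + straddle(ORACLE_FIBRE["AOAC"])
    proteins = [0.0] + straddle(ORACLE_PROTEIN)

    profiles = []
    cycle = itertools.count()
    # dense grid over the first three A-nutrients (21^3 combinations) ...
    for energy, satfat, sugar in itertools.product(energies, satfats, sugars):
        i = next(cycle)
        profiles.append(NutrientProfile(
            energy_kj=energy, satfat_g=satfat, sugar_g=sugar,
            sodium_mg=sodiums[i % len(sodiums)],
            fibre_g=fibres[i % len(fibres)],
            protein_g=proteins[i % len(proteins)],
            fvn_pct=fvns[i % len(fvns)],
            fibre_basis="AOAC",
        ))
    # ... plus a sodium/credit-focused grid so every component pair straddles
    for sodium, fvn, fibre in itertools.product(sodiums[1:], fvns, fibres):
        i = next(cycle)
        profiles.append(NutrientProfile(
            energy_kj=energies[i % len(energies)],
            satfat_g=satfats[i % len(satfats)],
            sugar_g=sugars[i % len(sugars)],
            sodium_mg=sodium, fibre_g=fibre,
            protein_g=proteins[i % len(proteins)],
            fvn_pct=fvn,
            fibre_basis="NSP" if i % 2 else "AOAC",
        ))
    return profiles


@pytest.fixture(scope="session")
def boundary_profiles():
    return boundary_straddling_profiles()
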