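"""Orthonormal wavelet filter banks for the D, LA and C families.

Provides the compactly supported orthogonal scaling/wavelet coefficient
pairs used throughout the package: Daubechies Extremal Phase (``D``,
lengths 2-20), Daubechies Least Asymmetric / symlet (``LA``, lengths
8-20) and Coiflet (``C``, lengths 6, 12, 18, 24).

Coefficients are tabulated at double precision in the Percival-Walden
convention: the scaling filter ``g`` sums to sqrt(2) and the wavelet
filter is the quadrature mirror ``h[l] = (-1)**l * g[L-1-l]``.  Every
pair is validated against the orthonormality identities at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletFilter",
    "UnsupportedFilterError",
    "make_filter",
    "vanishing_moments",
    "admissible_lengths",
    "ADMISSIBLE",
    "FAMILIES",
]

FAMILIES = ("D", "LA", "C")

#: Admissible filter lengths per family.
ADMISSIBLE = {
    "D": tuple(range(2, 21, 2)),
    "LA": tuple(range(8, 21, 2)),
    "C": (6, 12, 18, 24),
}

# Scaling-filter coefficients g (Percival-Walden convention: sum(g)=sqrt(2)),
# tabulated at full double precision.
_SCALING: dict[tuple[str, int], tuple[float, ...]] = {
    ("D", 2): (
        0.7071067811865476,
        0.7071067811865476,
    ),
    ("D", 4): (
        0.48296291314453416,
        0.8365163037378079,
        0.2241438680420134,
        -0.12940952255126037,
    ),
    ("D", 6): (
        0.33267055295008263,
        0.8068915093110925,
        0.45987750211849154,
        -0.13501102001025458,
        -0.08544127388202666,
        0.03522629188570953,
    ),
    ("D", 8): (
        0.2303778133088965,
        0.7148465705529157,
        0.6308807679298589,
        -0.027983769416859854,
        -0.18703481171909309,
        0.030841381835560764,
        0.0328830116668852,
        -0.010597401785069032,
    ),
    ("D", 10): (
        0.16010239797419293,
        0.6038292697971896,
        0.7243085284377729,
        0.13842814590132074,
        -0.24229488706638203,
        -0.032244869584638375,
        0.07757149384004572,
        -0.006241490212798274,
        -0.012580751999081999,
        0.0033357252854737712,
    ),
    ("D", 12): (
        0.11154074335010947,
        0.49462389039845306,
        0.7511339080210954,
        0.31525035170919763,
        -0.22626469396543983,
        -0.12976686756726194,
        0.09750160558732304,
        0.027522865530305727,
        -0.03158203931748603,
        0.0005538422011614961,
        0.004777257510945511,
        -0.0010773010853084796,
    ),
    ("D", 14): (
        0.07785205408500918,
        0.3965393194819173,
        0.7291320908462351,
        0.4697822874051931,
        -0.14390600392856498,
        -0.22403618499387498,
        0.07130921926683026,
        0.08061260915108308,
        -0.03802993693501441,
        -0.01657454163066688,
        0.01255099855609984,
        0.0004295779729213665,
        -0.0018016407040474908,
        0.00035371379997452024,
    ),
    ("D", 16): (
        0.05441584224310401,
        0.31287159091429995,
        0.6756307362972898,
        0.5853546836542067,
        -0.015829105256349306,
        -0.2840155429615469,
        0.0004724845739132828,
        0.12874742662047847,
        -0.017369301001807547,
        -0.044088253930794755,
        0.013981027917398282,
        0.008746094047405777,
        -0.004870352993451574,
        -0.00039174037337694705,
        0.0006754494064505693,
        -0.00011747678412476953,
    ),
    ("D", 18): (
        0.038077947363878345,
        0.24383467461259034,
        0.6048231236901112,
        0.6572880780513005,
        0.13319738582500756,
        -0.2932737832791749,
        -0.09684078322297646,
        0.14854074933810638,
        0.03072568147933338,
        -0.06763282906132997,
        0.00025094711483145197,
        0.022361662123679096,
        -0.004723204757751397,
        -0.00428150368246343,
        0.0018476468830562265,
        0.00023038576352319597,
        -0.0002519631889427101,
        3.93473203162716e-05,
    ),
    ("D", 20): (
        0.026670057900555554,
        0.1881768000776915,
        0.5272011889317256,
        0.6884590394536035,
        0.2811723436605775,
        -0.24984642432731538,
        -0.19594627437737705,
        0.12736934033579325,
        0.09305736460357235,
        -0.07139414716639708,
        -0.029457536821875813,
        0.033212674059341,
        0.0036065535669561697,
        -0.010733175483330575,
        0.001395351747052901,
        0.001992405295185056,
        -0.0006858566949597116,
        -0.00011646685512928545,
        9.358867032006959e-05,
        -1.3264202894521244e-05,
    ),
    ("LA", 8): (
        0.0322231006040427,
        -0.012603967262037833,
        -0.09921954357684722,
        0.29785779560527736,
        0.8037387518059161,
        0.49761866763201545,
        -0.02963552764599851,
        -0.07576571478927333,
    ),
    ("LA", 10): (
        0.019538882735286728,
        -0.021101834024758855,
        -0.17532808990845047,
        0.01660210576452232,
        0.6339789634582119,
        0.7234076904024206,
        0.1993975339773936,
        -0.039134249302383094,
        0.029519490925774643,
        0.027333068345077982,
    ),
    ("LA", 12): (
        -0.007800708325034148,
        0.0017677118642428036,
        0.04472490177066578,
        -0.021060292512300564,
        -0.07263752278646252,
        0.3379294217276218,
        0.787641141030194,
        0.4910559419267466,
        -0.048311742585633,
        -0.11799011114819057,
        0.0034907120842174702,
        0.015404109327027373,
    ),
    ("LA", 14): (
        0.010268176708511255,
        0.004010244871533663,
        -0.10780823770381774,
        -0.14004724044296152,
        0.2886296317515146,
        0.767764317003164,
        0.5361019170917628,
        0.017441255086855827,
        -0.049552834937127255,
        0.0678926935013727,
        0.03051551316596357,
        -0.01263630340325193,
        -0.0010473848886829163,
        0.002681814568257878,
    ),
    ("LA", 16): (
        0.0018899503327594609,
        -0.0003029205147213668,
        -0.01495225833704823,
        0.003808752013890615,
        0.049137179673607506,
        -0.027219029917056003,
        -0.05194583810770904,
        0.3644418948353314,
        0.7771857517005235,
        0.4813596512583722,
        -0.061273359067658524,
        -0.1432942383508097,
        0.007607487324917605,
        0.03169508781149298,
        -0.0005421323317911481,
        -0.0033824159510061256,
    ),
    ("LA", 18): (
        0.0010694900329086053,
        -0.0004731544986800831,
        -0.010264064027633142,
        0.008859267493400484,
        0.06207778930288603,
        -0.018233770779395985,
        -0.19155083129728512,
        0.035272488035271894,
        0.6173384491409358,
        0.717897082764412,
        0.238760914607303,
        -0.05456895843083407,
        0.0005834627461258068,
        0.03022487885827568,
        -0.01152821020767923,
        -0.013271967781817119,
        0.0006197808889855868,
        0.0014009155259146807,
    ),
    ("LA", 20): (
        -0.0004593294210046588,
        5.7036083618494284e-05,
        0.004593173585311828,
        -0.0008043589320165449,
        -0.02035493981231129,
        0.005764912033581909,
        0.04999497207737669,
        -0.0319900568824278,
        -0.03553674047381755,
        0.38382676106708546,
        0.7695100370211071,
        0.47169066693843925,
        -0.07088053578324385,
        -0.15949427888491757,
        0.011609893903711381,
        0.0459272392310922,
        -0.0014653825813050513,
        -0.008641299277022422,
        9.563267072289475e-05,
        0.0007701598091144901,
    ),
    ("C", 6): (
        -0.07273261951252645,
        0.3378976624574818,
        0.8525720202116004,
        0.3848648468648578,
        -0.07273261951252645,
        -0.015655728135791993,
    ),
    ("C", 12): (
        0.01638733646320364,
        -0.04146493678687178,
        -0.0673725547237256,
        0.3861100668227629,
        0.8127236354494135,
        0.4170051844232391,
        -0.07648859907828076,
        -0.05943441864643109,
        0.02368017194684777,
        0.005611434819368834,
        -0.0018232088709110323,
        -0.000720549445520347,
    ),
    ("C", 18): (
        -0.003793512864380802,
        0.007782596425672746,
        0.023452696142077168,
        -0.06577191128146936,
        -0.06112339000297255,
        0.40517690240911824,
        0.7937772226260872,
        0.42848347637737,
        -0.07179982161915484,
        -0.08230192710629983,
        0.03455502757329774,
        0.015880544863669452,
        -0.009007976136730624,
        -0.0025745176881367972,
        0.0011175187708306303,
        0.0004662169598204029,
        -7.0983302506379e-05,
        -3.459977319727278e-05,
    ),
    ("C", 24): (
        0.000892313902537003,
        -0.001629492425226786,
        -0.007346167936268051,
        0.01606894713157503,
        0.02668230466960483,
        -0.08126671024919373,
        -0.05607731960356926,
        0.41530842700068227,
        0.7822389344242826,
        0.43438603311435653,
        -0.06662747236681717,
        -0.09622042453595264,
        0.03933442260558915,
        0.02508225333794961,
        -0.015211728187697211,
        -0.0056582838001308835,
        0.0037514346971460866,
        0.0012665610789256603,
        -0.0005890202246332165,
        -0.0002599743371222568,
        6.233885431278719e-05,
        3.1229861599195265e-05,
        -3.259647940030751e-06,
        -1.7849909144933469e-06,
    ),
}


class UnsupportedFilterError(ValueError):
    """Raised for a (family, length) pair outside the admissible set."""


def admissible_lengths(family: str) -> tuple[int, ...]:
    """Return the admissible filter lengths for ``family``."""
    if family not in ADMISSIBLE:
        raise UnsupportedFilterError(
            f"unknown family {family!r}; families are {FAMILIES}"
        )
    return ADMISSIBLE[family]


@dataclass(frozen=True)
class WaveletFilter:
    """An orthonormal scaling/wavelet filter pair.

    Attributes
    ----------
    family : str
        One of ``"D"`` (Daubechies Extremal Phase), ``"LA"``
        (Least Asymmetric) or ``"C"`` (Coiflet).
    length : int
        Number of coefficients ``L`` (even).
    scaling_coeffs : ndarray
        Low-pass filter ``g`` with ``sum(g) = sqrt(2)``.
    wavelet_coeffs : ndarray
        High-pass quadrature mirror ``h``, ``sum(h) = 0``.
    """

    family: str
    length: int
    scaling_coeffs: np.ndarray = field(repr=False)
    wavelet_coeffs: np.ndarray = field(repr=False)

    @property
    def name(self) -> str:
        """Short label in the D4 / LA8 / C6 style."""
        return f"{self.family}{self.length}"

    def validate(self, atol: float = 1e-10) -> None:
        """Check the orthonormal filter-bank identities.

        Verifies unit energy, sum conditions, the quadrature-mirror
        relation and orthogonality of ``g`` to its even shifts.
        """
        g, h, L = self.scaling_coeffs, self.wavelet_coeffs, self.length
        if L % 2 or L != g.size or L != h.size:
            raise ValueError(f"inconsistent filter length {L}")
        if abs(g.sum() - np.sqrt(2.0)) > atol:
            raise ValueError(f"{self.name}: sum(g) != sqrt(2)")
        if abs(h.sum()) > atol:
            raise ValueError(f"{self.name}: sum(h) != 0")
        for v, nm in ((g, "g"), (h, "h")):
            if abs(v @ v - 1.0) > atol:
                raise ValueError(f"{self.name}: ||{nm}||^2 != 1")
        signs = (-1.0) ** np.arange(L)
        if np.max(np.abs(h - signs * g[::-1])) > atol:
            raise ValueError(f"{self.name}: QMF relation violated")
        for k in range(1, L // 2):
            if abs(g[: L - 2 * k] @ g[2 * k :]) > atol:
                raise ValueError(f"{self.name}: g not orthogonal to shift {2 * k}")

    def transfer_functions(self, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Squared-gain functions ``|G(f)|^2`` and ``|H(f)|^2``.

        For an orthonormal pair these tile the spectrum:
        ``|G(f)|^2 + |H(f)|^2 = 2`` for every frequency ``f`` (in cycles
        per sample).
        """
        ell = np.arange(self.length)
        phase = np.exp(-2j * np.pi * np.outer(freqs, ell))
        G = phase @ self.scaling_coeffs
        H = phase @ self.wavelet_coeffs
        return np.abs(G) ** 2, np.abs(H) ** 2

    def to_text(self, path) -> None:
        """Write the pair as two-column (index, value) delimited text."""
        with open(path, "w") as fh:
            fh.write(f"# {self.name} scaling filter g then wavelet filter h\n")
            for label, v in (("g", self.scaling_coeffs), ("h", self.wavelet_coeffs)):
                for i, x in enumerate(v):
                    fh.write(f"{label}{i}\t{float(x)!r}\n")


def make_filter(family: str, length: int) -> WaveletFilter:
    """Return the validated filter pair for ``(family, length)``.

    Raises
    ------
    UnsupportedFilterError
        If the combination is not defined, naming the admissible set
        (e.g. the LA family starts at length 8 and Coiflets exist only
        at multiples of 6).
    """
    lengths = admissible_lengths(family)
    if length not in lengths:
        raise UnsupportedFilterError(
            f"{family}{length} is not defined; admissible lengths for "
            f"{family} are {lengths}"
        )
    g = np.asarray(_SCALING[(family, length)], dtype=float)
    h = (-1.0) ** np.arange(length) * g[::-1]
    filt = WaveletFilter(family, length, g, h)
    filt.validate()
    return filt


def vanishing_moments(filt: WaveletFilter, atol: float = 1e-8) -> int:
    """Number of vanishing moments of the wavelet filter.

    The largest ``p`` such that ``sum_l l**m h[l] = 0`` for all
    ``m < p``.  Moment sums are evaluated on coefficients scaled to
    unit max so the tolerance is meaningful for long filters.
    """
    h = filt.wavelet_coeffs
    ell = np.arange(filt.length, dtype=float)
    p = 0
    for m in range(filt.length):
        moment = (ell**m) @ h
        # normalise by the scale of the summands
        scale = max(np.max(np.abs(ell**m * h)), 1.0)
        if abs(moment) / scale > atol:
            break
        p += 1
    return p


def all_filters():
    """Iterate over every admissible (family, length) filter."""
    for family, lengths in ADMISSIBLE.items():
        for L in lengths:
            yield make_filter(family, L)
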