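import numpy as np
import pytest

from semirigid import PlantedSpec, generate_planted_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_matrix(rng, n, scale=1.0):
    """Random symmetric zero-diagonal non-negative matrix."""
    m = rng.random((n, n)) * scale
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


def block_matrix(sizes, within=0.0, between=1.0):
    """Block-structured dissimilarity with perfect blocks by default."""
    n = sum(sizes)
    m = np.full((n, n), between)
    start = 0
    for s in sizes:
        m[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def two_block_matrix():
    return block_matrix([2, 2])


@pytest.fixture
def small_planted():
    spec = PlantedSpec(
        n_domains=2, atoms_per_domain=5, domain_motion_amplitude=0.1,
        atom_jitter_sigma=0.0, n_frames=40, dt_frame=20.0, seed=99,
    )
    return generate_planted_trajectory(spec)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the code paths they check)


def quaternion_superpose_rmsd(mobile, reference):
    """Horn's closed-form quaternion solution for the minimum RMSD.

    Independent of the SVD-based implementation under test.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    n = mob.shape[0]
    msd = (np.sum(mob ** 2) + np.sum(ref ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def pair_counting_ari(a, b):
    """Adjusted Rand index by explicit enumeration of all atom pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def tcl_syntax_ok(script):
    """Minimal Tcl checker: balanced braces/brackets and quotes per line."""
    depth_brace = depth_bracket = 0
    for line in script.splitlines():
        if line.count('"') % 2 != 0:
            return False
        for ch in line:
            if ch == "{":
                depth_brace += 1
            elif ch == "}":
                depth_brace -= 1
            elif ch == "[":
                depth_bracket += 1
            elif ch == "]":
                depth_bracket -= 1
            if depth_brace < 0 or depth_bracket < 0:
                return False
    return depth_brace == 0 and depth_bracket == 0
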