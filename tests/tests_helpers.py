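"""Shared constructors for statistics tests."""

from hydrotraits.stats import GLMFit


def fits_with_aics(aics):
    return [
        GLMFit(
            formula=(f"p{i}",), coefficients={}, coefficient_se={},
            aic=float(a), mcfadden_r2=0.5, deviance_explained=0.5,
            vif={f"p{i}": 1.0}, n=10,
        )
        for i, a in enumerate(aics)
    ]
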