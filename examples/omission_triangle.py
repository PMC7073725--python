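"""Omission triangle tests: exact binomial significance of each removal.

Builds a small omission battery (each test removes one ester from the full
reconstitution; 60 triangle presentations each) and reports the exact
upper-tail binomial p-value and star label per test.
"""

from aromix import TriangleTest, omission_report

battery = [
    TriangleTest("Test 1", n_trials=60, n_correct=36, omitted_compound="ethyl acetate"),
    TriangleTest("Test 2", n_trials=60, n_correct=30, omitted_compound="ethyl propionate"),
    TriangleTest("Test 3", n_trials=60, n_correct=27, omitted_compound="isoamyl acetate"),
    TriangleTest("Test 4", n_trials=60, n_correct=21, omitted_compound="ethyl caprate"),
]
report = omission_report(battery)
print(report.to_string(index=False))
# With chance rate 1/3, 36/60 correct is perceived at the 0.1% level (***):
# removing that ester changes the aroma; 21/60 is indistinguishable from
# guessing (=), so that ester is not individually critical.
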