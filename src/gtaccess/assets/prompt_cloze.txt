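Read the clinical note excerpts and complete the sentence at the end.

Categories: Yes (testing done, recommended, or counseling referral made, with at least one relevant VA provider visit); No (relevant VA provider seen, no Yes criteria met); Not applicable (all breast cancer care in the community); Not sure (considered for testing but criteria not met).

Clinical note excerpts:
{{document}}

Completion (fill the blank with one category, keeping the scaffold):
ANSWER: ____
RATIONALE: ____
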