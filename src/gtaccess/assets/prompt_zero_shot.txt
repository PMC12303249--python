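You are reviewing consolidated excerpts from the clinical notes of one patient treated for breast cancer. Decide whether the patient had access to germline genetic testing. Choose exactly one category:

Yes: the patient had germline genetic testing, testing was recommended, or the patient was referred through a consult to a genomic medicine service, clinical cancer genetics, or community care for genetic counseling, and the patient was seen by at least one relevant VA provider (for example medical oncology, radiation oncology, or surgery).
No: the patient was seen by at least one relevant VA provider and none of the criteria under Yes were met.
Not applicable: all breast cancer care took place in the community, meaning the patient was not seen by any relevant VA provider, regardless of the criteria under Yes.
Not sure: the patient was seen by a relevant VA provider and was considered for germline genetic testing, but testing was not performed because the patient did not meet criteria.

Answer in exactly this format, with no other text before the answer line:
ANSWER: <Yes | No | Not applicable | Not sure>
RATIONALE: <one short sentence quoting the decisive evidence>

Clinical note excerpts for this patient:
{{document}}
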