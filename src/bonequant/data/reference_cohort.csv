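patient_id,lesion_id,sex,age,agent,illness,stage
P01,L01,M,84,Zoledronate -> Denosumab,Prostate cancer,3
P02,L02,F,77,Minodronate,Primary osteoporosis,2
P03,L03,M,87,Denosumab,Prostate cancer,2
P04,L04,F,78,Minodronate,Primary osteoporosis,2
P05,L05,M,73,Zoledronate,Lung cancer,3
P05,L06,M,73,Zoledronate,Lung cancer,1
P06,L07,F,63,Denosumab,Lung cancer,2
P07,L08,F,67,Alendronate,Glucocorticoid-induced osteoporosis,2
P08,L09,F,68,Zoledronate -> Denosumab,Breast cancer,2
P08,L10,F,68,Zoledronate -> Denosumab,Breast cancer,1
P09,L11,F,68,Zoledronate -> Risedronate -> Minodronate,Glucocorticoid-induced osteoporosis,2
P10,L12,F,68,Zoledronate,Breast cancer,2
P11,L13,F,79,Alendronate -> Risedronate -> Ibandronate,Glucocorticoid-induced osteoporosis,2
P12,L14,M,80,Zoledronate -> Denosumab,Prostate cancer,2
P13,L15,F,83,Zoledronate -> Denosumab,Primary osteoporosis,1
P14,L16,F,72,Denosumab,Breast cancer,2
P15,L17,M,71,Denosumab,Lung cancer,2
P16,L18,F,55,Zoledronate,Multiple myeloma,2
P17,L19,M,72,Denosumab,Prostate cancer,3
P18,L20,F,67,Denosumab,Breast cancer,3
P19,L21,F,69,Zoledronate -> Denosumab,Breast cancer,2
P20,L22,F,79,Alendronate,Glucocorticoid-induced osteoporosis,2
P21,L23,F,58,Denosumab,Breast cancer,2
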