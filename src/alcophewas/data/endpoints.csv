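endpoint_id,label,codes,who_flag
A15_B90,Tuberculosis,A15-A19;B90,1
C00_14,Cancer of lip oral cavity and pharynx,C00-C14,1
C15,Esophageal cancer,C15,1
C16,Stomach cancer,C16,0
C18,Colon cancer,C18,1
C19_20,Rectal cancer,C19;C20,1
C22,Liver cancer,C22,1
C32,Laryngeal cancer,C32,1
C34,Lung cancer,C34,0
D69,Purpura and other hemorrhagic conditions,D69,0
E04,Other nontoxic goiter,E04,0
E10_14,Diabetes mellitus,E10-E14,1
F10,Alcohol-related mental and behavioral disorders,F10,1
F32_33,Depressive episodes,F32;F33,0
G40_41,Epilepsy,G40;G41,1
G45,Transient cerebral ischemic attacks,G45,1
H25_26,Cataract,H25;H26,0
I10_11,Hypertensive diseases,I10;I11,1
I21,Acute myocardial infarction,I21,1
I25,Chronic ischemic heart disease,I25,1
I42,Cardiomyopathy,I42,1
I48,Atrial fibrillation and flutter,I48,0
I61,Intracerebral hemorrhage,I61,1
I63,Cerebral infarction,I63,1
I65_66,Occlusion and stenosis of cerebral arteries,I65;I66,1
I67,Other cerebrovascular diseases,I67,1
I69,Sequelae of cerebrovascular disease,I69,1
J12_18,Pneumonia,J12-J18,1
J44,Other chronic obstructive pulmonary disease,J44,0
K21,Gastroesophageal reflux disease,K21,0
K25,Gastric ulcer,K25,0
K29,Gastritis and duodenitis,K29,0
K40,Inguinal hernia,K40,0
K70,Alcoholic liver disease,K70,1
K74,Liver cirrhosis,K74,1
K80,Cholelithiasis,K80,0
K85_86,Pancreatitis,K85;K86,1
M10,Gout,M10,0
N20,Calculus of kidney and ureter,N20,0
N40,Hyperplasia of prostate,N40,0
R07,Pain in throat and chest,R07,0
S22,Fracture of ribs sternum and thoracic spine,S22,0
S42,Fracture of shoulder and upper arm,S42,0
S72,Fracture of femur,S72,0
V01_99,Transport accidents,V01-V99,1
W00_19,Falls,W00-W19,1
X60_84,Intentional self-harm,X60-X84,1
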