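@prefix : <http://example.org/toxlift/endpoint#> .
@prefix dc: <http://purl.org/dc/elements/1.1/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

:AquaticToxicity rdf:type owl:Class .
:AquaticToxicity rdfs:label "AquaticToxicity" .
:AquaticToxicity rdfs:subClassOf :ToxicityStudyType .
:Carcinogenicity rdf:type owl:Class .
:Carcinogenicity rdfs:label "Carcinogenicity" .
:Carcinogenicity rdfs:subClassOf :ToxicityStudyType .
:Chronic rdf:type owl:Class .
:Chronic rdfs:label "Chronic" .
:Chronic rdfs:subClassOf :RepeatedDoseToxicity .
:InVitroBacterialMutagenicity rdf:type owl:Class .
:InVitroBacterialMutagenicity rdfs:label "InVitroBacterialMutagenicity" .
:InVitroBacterialMutagenicity rdfs:subClassOf :ToxicityStudyType .
:InVivoMicronucleusMutagenicity rdf:type owl:Class .
:InVivoMicronucleusMutagenicity rdfs:label "InVivoMicronucleusMutagenicity" .
:InVivoMicronucleusMutagenicity rdfs:subClassOf :ToxicityStudyType .
:ModeOfAction rdf:type owl:Class .
:ModeOfAction rdfs:label "ModeOfAction" .
:ModeOfAction rdfs:subClassOf :TestResult .
:RepeatedDoseToxicity rdf:type owl:Class .
:RepeatedDoseToxicity rdfs:label "RepeatedDoseToxicity" .
:RepeatedDoseToxicity rdfs:subClassOf :ToxicityStudyType .
:RouteOfExposure rdf:type owl:Class .
:RouteOfExposure rdfs:label "RouteOfExposure" .
:RouteOfExposure rdfs:subClassOf :TestSystem .
:Sex rdf:type owl:Class .
:Sex rdfs:label "Sex" .
:Sex rdfs:subClassOf :TestSystem .
:Species rdf:type owl:Class .
:Species rdfs:label "Species" .
:Species rdfs:subClassOf :TestSystem .
:Strain rdf:type owl:Class .
:Strain rdfs:label "Strain" .
:Strain rdfs:subClassOf :TestSystem .
:SubAcute rdf:type owl:Class .
:SubAcute rdfs:label "SubAcute" .
:SubAcute rdfs:subClassOf :RepeatedDoseToxicity .
:SubChronic rdf:type owl:Class .
:SubChronic rdfs:label "SubChronic" .
:SubChronic rdfs:subClassOf :RepeatedDoseToxicity .
:TargetSite rdf:type owl:Class .
:TargetSite rdfs:label "TargetSite" .
:TargetSite rdfs:subClassOf :TestResult .
:TestCall rdf:type owl:Class .
:TestCall rdfs:label "TestCall" .
:TestCall rdfs:subClassOf :TestResult .
:TestResult rdf:type owl:Class .
:TestResult rdfs:comment "The recorded outcome of a toxicity study." .
:TestResult rdfs:label "TestResult" .
:TestSystem rdf:type owl:Class .
:TestSystem rdfs:comment "The biological system and exposure design of a study." .
:TestSystem rdfs:label "TestSystem" .
:ToxicityMeasure rdf:type owl:Class .
:ToxicityMeasure rdfs:label "ToxicityMeasure" .
:ToxicityMeasure rdfs:subClassOf :TestResult .
:ToxicityStudyType rdf:type owl:Class .
:ToxicityStudyType rdfs:comment "Category of toxicity study an endpoint belongs to." .
:ToxicityStudyType rdfs:label "ToxicityStudyType" .
:hasTestResult rdf:type owl:ObjectProperty .
:hasTestResult rdfs:domain :ToxicityStudyType .
:hasTestResult rdfs:range :TestResult .
:hasTestSystem rdf:type owl:ObjectProperty .
:hasTestSystem rdfs:domain :ToxicityStudyType .
:hasTestSystem rdfs:range :TestSystem .
<http://example.org/toxlift/endpoint> rdf:type owl:Ontology .
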